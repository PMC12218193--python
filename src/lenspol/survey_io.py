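"""Survey table reading, exclusion rules, identity assignment, and wave IO.

The reader is survey-agnostic: a delimited text table with a header row,
plus a configuration mapping column roles (wave, weight, party, closeness,
opinion items). The exclusion pipeline mirrors common survey practice —
drop respondents with invalid answers on any analysis item, with a
disqualifying answer on a configured item (e.g. denying that the attitude
object exists at all), with out-of-scope party affiliations, or refusing
the party question — and records each rule's count in an order-auditable
:class:`FilterLedger`.

Identity assignment maps party codes to group labels; respondents with no
party preference, or who feel "not at all" close to their preferred party,
become nonpartisans with the reserved label ``"None"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .opinion_model import NONPARTISAN_LABEL, LikertScheme, OpinionWave, map_likert_to_unit

__all__ = [
    "FilterLedger",
    "apply_filters",
    "assign_identities",
    "read_survey_table",
    "read_wave",
    "table_to_wave",
    "write_wave",
]


@dataclass
class FilterLedger:
    """Ordered record of respondent exclusions; counts always reconcile."""

    n_input: int
    rules: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(k for _, k in self.rules)

    def record(self, rule_name: str, n_excluded: int) -> None:
        self.rules.append((rule_name, int(n_excluded)))

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "rules": [{"rule": r, "n_excluded": k} for r, k in self.rules],
            "n_retained": self.n_retained,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def read_survey_table(path, config: dict) -> pd.DataFrame:
    """Read a delimited survey table and check the configured columns exist.

    The delimiter is taken from ``config["delimiter"]`` if present, else
    sniffed (comma / tab / semicolon). No filtering is performed.
    """
    sep = config.get("delimiter")
    try:
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python")
        else:
            df = pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise
    except Exception as exc:  # surface parse errors with the path
        raise ValueError(f"could not parse survey table {path}: {exc}") from exc

    required = list(config.get("items", []))
    for role in ("wave", "weight", "party", "closeness"):
        col = config.get(role)
        if col is not None:
            required.append(col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"survey table {path} is missing configured column(s): {missing}"
        )
    return df


def apply_filters(
    table: pd.DataFrame, rules: dict
) -> tuple[pd.DataFrame, FilterLedger]:
    """Apply the exclusion rules in their declared order.

    ``rules`` keys (all optional; unknown keys are an error):

    - ``items``: list of opinion item columns; with ``scheme`` (a
      :class:`LikertScheme`), rows whose item answers are missing codes or
      NaN are dropped (``invalid_item_response``).
    - ``disqualify``: ``{"item": col, "codes": [...]}`` — rows giving a
      disqualifying answer are dropped (``disqualifying_answer``).
    - ``party``: party column name, with ``allowed_parties`` (codes kept,
      besides missing) — others dropped (``party_out_of_scope``) — and
      ``refusal_codes`` dropped as ``party_refusal``.

    Each rule's count is taken against the survivors of the previous rule,
    so the ledger reconciles exactly and re-applying the same rules to the
    filtered table excludes nothing.
    """
    known = {"items", "scheme", "disqualify", "party", "allowed_parties", "refusal_codes"}
    unknown = set(rules) - known
    if unknown:
        raise ValueError(f"unknown filter rule(s): {sorted(unknown)}")

    df = table.copy()
    ledger = FilterLedger(n_input=len(df))

    dq = rules.get("disqualify")
    items = rules.get("items")
    if items:
        scheme: LikertScheme = rules.get("scheme") or LikertScheme()
        ok = np.ones(len(df), dtype=bool)
        for col in items:
            admissible = list(scheme.levels)
            if dq and dq["item"] == col:
                # a disqualifying answer is substantive, not invalid; it is
                # counted by its own rule next
                admissible += list(dq["codes"])
            vals = pd.to_numeric(df[col], errors="coerce")
            ok &= vals.isin(admissible).to_numpy()
        ledger.record("invalid_item_response", (~ok).sum())
        df = df[ok]

    if dq:
        bad = pd.to_numeric(df[dq["item"]], errors="coerce").isin(list(dq["codes"]))
        ledger.record("disqualifying_answer", bad.sum())
        df = df[~bad.to_numpy()]

    party_col = rules.get("party")
    if party_col is not None:
        allowed = rules.get("allowed_parties", [])
        refusals = set(rules.get("refusal_codes", []))
        vals = pd.to_numeric(df[party_col], errors="coerce")
        out_of_scope = (
            vals.notna()
            & ~vals.isin(list(allowed))
            & ~vals.isin(list(refusals))
        )
        ledger.record("party_out_of_scope", out_of_scope.sum())
        df = df[~out_of_scope.to_numpy()]
        vals = pd.to_numeric(df[party_col], errors="coerce")
        refused = vals.isin(list(refusals))
        ledger.record("party_refusal", refused.sum())
        df = df[~refused.to_numpy()]

    return df.reset_index(drop=True), ledger


def assign_identities(
    table: pd.DataFrame,
    party_map: dict,
    closeness_rule: dict | None = None,
    party_column: str = "party",
) -> list[str]:
    """Map party codes to group labels; the rest become nonpartisans.

    ``party_map`` maps party codes to labels. Respondents with no party
    preference (NaN) get the ``"None"`` label, as do those whose answer on
    the closeness column (``closeness_rule = {"column": ..., "not_close_codes":
    [...]}``) says they feel not at all close to their preferred party.
    A non-NaN party code absent from ``party_map`` is an error — such rows
    should have been excluded by the filters.
    """
    vals = pd.to_numeric(table[party_column], errors="coerce")
    codes = {float(k): v for k, v in party_map.items()}
    not_close = np.zeros(len(table), dtype=bool)
    if closeness_rule:
        cvals = pd.to_numeric(table[closeness_rule["column"]], errors="coerce")
        not_close = cvals.isin(list(closeness_rule.get("not_close_codes", []))).to_numpy()
    labels: list[str] = []
    for i, v in enumerate(vals):
        if pd.isna(v) or not_close[i]:
            labels.append(NONPARTISAN_LABEL)
        elif float(v) in codes:
            labels.append(codes[float(v)])
        else:
            raise ValueError(
                f"row {i}: party code {v!r} is not in the party map and was "
                "not excluded by the filters"
            )
    return labels


def table_to_wave(
    table: pd.DataFrame,
    config: dict,
    scheme: LikertScheme | None = None,
    wave_label: str | None = None,
) -> OpinionWave:
    """Build an :class:`OpinionWave` from a filtered survey table.

    Items are mapped to the unit interval through ``scheme``; identities
    come from ``config["party_map"]`` (with the optional closeness rule) or,
    if absent, verbatim from an ``identity`` column. Weights default to 1
    when no weight column is configured.
    """
    scheme = scheme or LikertScheme()
    items = list(config["items"])
    raw = table[items].to_numpy()
    values, valid = map_likert_to_unit(raw, scheme)
    if not valid.all():
        raise ValueError(
            "table still contains missing item answers; run apply_filters first"
        )
    if "party_map" in config:
        identities = assign_identities(
            table,
            config["party_map"],
            config.get("closeness_rule"),
            party_column=config.get("party", "party"),
        )
    else:
        identities = [str(g) for g in table[config.get("identity", "identity")]]
    wcol = config.get("weight")
    weights = (
        table[wcol].to_numpy(dtype=float) if wcol is not None else np.ones(len(table))
    )
    if wave_label is None:
        wc = config.get("wave")
        if wc is not None and wc in table.columns and len(table):
            wave_label = str(table[wc].iloc[0])
        else:
            wave_label = "wave"
    return OpinionWave(
        wave_label=wave_label,
        opinions=values,
        identities=identities,
        weights=weights,
        item_names=items,
    )


def write_wave(wave: OpinionWave, path) -> None:
    """Write a wave to the documented delimited layout (lossless round-trip).

    Columns: ``wave``, ``identity``, ``weight``, then one unit-interval
    opinion column per item, full float precision.
    """
    df = pd.DataFrame(
        {"wave": wave.wave_label, "identity": wave.identities, "weight": wave.weights}
    )
    for j, name in enumerate(wave.item_names):
        df[name] = wave.opinions[:, j]
    df.to_csv(path, index=False)


def read_wave(path) -> OpinionWave:
    """Read a wave written by :func:`write_wave` (lossless float parsing)."""
    df = pd.read_csv(path, float_precision="round_trip")
    fixed = ["wave", "identity", "weight"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"wave file {path} is missing column(s): {missing}")
    items = [c for c in df.columns if c not in fixed]
    return OpinionWave(
        wave_label=str(df["wave"].iloc[0]),
        opinions=df[items].to_numpy(dtype=float),
        identities=[str(g) for g in df["identity"]],
        weights=df["weight"].to_numpy(dtype=float),
        item_names=items,
    )
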