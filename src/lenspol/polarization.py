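"""Mean perceived disagreement and the polarization decomposition.

Perceived disagreement in a wave is the weighted average, over ordered
respondent pairs (i, j), i != j, of the distance perceiver i measures to j
through the lens of i's identity group:

    dbar(X, L) = sum_{i != j} w_i w_j d(x_i, x_j | L_{g(i)}) / sum_{i != j} w_i w_j

(with unit weights this is the plain 1/(n(n-1)) double sum). Perceived
polarization between two waves is P = dbar(t2) - dbar(t1), and it splits
exactly into a pure (opinion-driven) and a lens-specific (perception-driven)
component via the telescoping identity

    P  = [dbar(X2, L2) - dbar(X2, L1)] + [dbar(X2, L1) - dbar(X1, L1)]
       =        P2                  +          P1.

With lenses refitted to each wave's own in-group distribution (zero-delay
updating) the lens term is the instantaneous lens-specific polarization P2*.
The objective (Euclidean, identity-lens) counterpart of every quantity is
carried along as the neutral-observer benchmark.

Pair weighting uses the product w_i * w_j normalized over included ordered
pairs (self-pairs excluded) — the standard U-statistic weighting; per-group
values restrict the *perceiving* side i to one group while j ranges over the
whole wave, so the weighted combination of per-group means recovers the
population mean exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .lens import LensSet, build_lens_set
from .opinion_model import OpinionWave

__all__ = [
    "DisagreementReport",
    "PolarizationDecomposition",
    "decompose",
    "decompose_instantaneous",
    "mean_disagreement",
    "perceived_polarization",
]

_BLOCK_ROWS = 1024  # cap cdist blocks at ~n * _BLOCK_ROWS doubles


@dataclass
class DisagreementReport:
    """Mean perceived disagreement for one (opinions, lenses) pairing."""

    opinions_wave: str
    lenses_wave: str
    item_names: list[str]
    population_mean: float
    per_group_mean: dict[str, float]
    per_group_pair_mass: dict[str, float]
    objective_mean: float
    n_pairs_effective: float
    squared: bool = False
    #: per-perceiver mean distances (perceiver-side projection), for SEs
    perceiver_means: np.ndarray | None = field(default=None, repr=False)
    perceiver_groups: list[str] | None = field(default=None, repr=False)
    perceiver_weights: np.ndarray | None = field(default=None, repr=False)

    def standard_error(self, group: str | None = None) -> float:
        """Design-based U-statistic (projection) standard error of the mean.

        Var(dbar) ~= 4 Var_w(dbar_i) / n_eff, with dbar_i the per-perceiver
        mean distance; restricted to one perceiver group when given.
        """
        if self.perceiver_means is None:
            raise ValueError("report was computed without perceiver means")
        d_i = self.perceiver_means
        w = self.perceiver_weights
        if group is not None:
            mask = np.asarray([g == group for g in self.perceiver_groups])
            d_i, w = d_i[mask], w[mask]
        n_eff = w.sum() ** 2 / (w ** 2).sum()
        mu = np.average(d_i, weights=w)
        var = np.average((d_i - mu) ** 2, weights=w)
        return 2.0 * math.sqrt(var / n_eff)

    def to_dict(self) -> dict:
        return {
            "opinions_wave": self.opinions_wave,
            "lenses_wave": self.lenses_wave,
            "item_names": list(self.item_names),
            "population_mean": self.population_mean,
            "per_group_mean": dict(self.per_group_mean),
            "per_group_pair_mass": dict(self.per_group_pair_mass),
            "objective_mean": self.objective_mean,
            "n_pairs_effective": self.n_pairs_effective,
            "squared": self.squared,
        }


def _group_pair_stats(y_g, y_all, w_g, w_all, w_g_sq_sum, squared):
    """Weighted sum of distances from perceivers (rows of y_g) to everyone.

    Self-pairs contribute zero distance; their weight mass w_i^2 is removed
    from the denominator. Returns (weighted sum, pair mass, per-perceiver
    weighted mean distances).
    """
    n_g = y_g.shape[0]
    w_total = w_all.sum()
    sums = np.empty(n_g)
    for start in range(0, n_g, _BLOCK_ROWS):
        stop = min(start + _BLOCK_ROWS, n_g)
        d = cdist(y_g[start:stop], y_all)
        if squared:
            d *= d
        sums[start:stop] = d @ w_all
    pair_sum = float(w_g @ sums)
    pair_mass = float(w_g.sum() * w_total - w_g_sq_sum)
    per_perceiver = sums / (w_total - w_g)  # mean over j != i for each i
    return pair_sum, pair_mass, per_perceiver


def mean_disagreement(
    opinions: OpinionWave,
    lenses: LensSet,
    perceiver_filter: str | None = None,
    squared: bool = False,
    compute_objective: bool = True,
) -> DisagreementReport:
    """Average pairwise distance each perceiver measures through their lens.

    Every ordered pair (i, j), i != j, contributes
    ``d(x_i, x_j | lens of group(i))`` with weight ``w_i * w_j``;
    ``perceiver_filter`` restricts the perceiving side i to one group while
    j still ranges over the whole wave. ``squared`` averages squared
    distances instead. The Euclidean (identity-metric) average is reported
    as ``objective_mean``.
    """
    if lenses.m != opinions.m:
        raise ValueError(
            f"wave has {opinions.m} items but lenses were fitted on {lenses.m}"
        )
    x = opinions.opinions
    w = np.asarray(opinions.weights, dtype=float)
    groups = opinions.groups()
    if perceiver_filter is not None:
        if perceiver_filter not in groups:
            raise ValueError(f"perceiver group {perceiver_filter!r} not in wave")
        groups = [perceiver_filter]

    per_group_mean: dict[str, float] = {}
    per_group_mass: dict[str, float] = {}
    total_sum = 0.0
    total_mass = 0.0
    n_perc = sum(int(opinions.group_mask(g).sum()) for g in groups)
    perceiver_means = np.empty(n_perc)
    perceiver_groups: list[str] = []
    perceiver_weights = np.empty(n_perc)
    pos = 0
    obj_sum = 0.0
    for g in groups:
        mask = opinions.group_mask(g)
        lens = lenses.lens_for(g)
        a = lens.whitener()
        y_all = x @ a
        s, mass, d_i = _group_pair_stats(
            y_all[mask], y_all, w[mask], w, float((w[mask] ** 2).sum()), squared
        )
        per_group_mean[g] = s / mass
        per_group_mass[g] = mass
        total_sum += s
        total_mass += mass
        n_g = int(mask.sum())
        perceiver_means[pos : pos + n_g] = d_i
        perceiver_weights[pos : pos + n_g] = w[mask]
        perceiver_groups.extend([g] * n_g)
        pos += n_g
        if compute_objective:
            s_obj, _, _ = _group_pair_stats(
                x[mask], x, w[mask], w, float((w[mask] ** 2).sum()), squared
            )
            obj_sum += s_obj

    return DisagreementReport(
        opinions_wave=opinions.wave_label,
        lenses_wave=lenses.fitted_on_wave,
        item_names=list(opinions.item_names),
        population_mean=total_sum / total_mass,
        per_group_mean=per_group_mean,
        per_group_pair_mass=per_group_mass,
        objective_mean=(obj_sum / total_mass) if compute_objective else float("nan"),
        n_pairs_effective=total_mass,
        squared=squared,
        perceiver_means=perceiver_means,
        perceiver_groups=perceiver_groups,
        perceiver_weights=perceiver_weights,
    )


def perceived_polarization(d1: DisagreementReport, d2: DisagreementReport) -> float:
    """Change in mean perceived disagreement, ``dbar(t2) - dbar(t1)``.

    Positive values mean respondents on average perceive opinions as
    diverging; negative values, converging.
    """
    if list(d1.item_names) != list(d2.item_names):
        raise ValueError(
            f"item sets differ: {d1.item_names} vs {d2.item_names}"
        )
    return d2.population_mean - d1.population_mean


@dataclass
class PolarizationDecomposition:
    """P = P1 + P2 between two waves, population and per-group.

    ``P1`` (pure) is the opinion-driven change seen through the earlier
    lenses; ``P2`` (lens-specific) is the perception change on the later
    opinions; under ``mode == "instantaneous"`` the ``P2`` field carries
    P2*. ``relative`` expresses each quantity as a fraction of the baseline
    disagreement dbar(t1) (per-group: of the group's own baseline).
    """

    t1: str
    t2: str
    P: float
    P1: float
    P2: float
    P_objective: float
    mode: str  # fixed | instantaneous | custom
    per_group: dict[str, dict[str, float]]
    relative: dict[str, float]
    per_group_relative: dict[str, dict[str, float]]
    baseline: DisagreementReport = field(repr=False)
    cross: DisagreementReport = field(repr=False)  # dbar(X2, L1)
    final: DisagreementReport = field(repr=False)  # dbar(X2, L2)

    def to_dict(self) -> dict:
        return {
            "t1": self.t1,
            "t2": self.t2,
            "mode": self.mode,
            "P": self.P,
            "P1": self.P1,
            "P2": self.P2,
            "P_objective": self.P_objective,
            "relative": dict(self.relative),
            "per_group": {g: dict(v) for g, v in self.per_group.items()},
            "per_group_relative": {
                g: dict(v) for g, v in self.per_group_relative.items()
            },
            "disagreement": {
                "baseline": self.baseline.to_dict(),
                "cross": self.cross.to_dict(),
                "final": self.final.to_dict(),
            },
        }

    def to_frame(self):
        """Tidy table: one row per (group, quantity), absolute and relative."""
        import pandas as pd

        rows = [
            {"group": "<population>", "quantity": q, "value": v,
             "relative_to_baseline": self.relative[q]}
            for q, v in (("P", self.P), ("P1", self.P1), ("P2", self.P2))
        ]
        for g, triple in self.per_group.items():
            for q in ("P", "P1", "P2"):
                rows.append(
                    {"group": g, "quantity": q, "value": triple[q],
                     "relative_to_baseline": self.per_group_relative[g][q]}
                )
        return pd.DataFrame(rows)


def decompose(
    wave1: OpinionWave,
    wave2: OpinionWave,
    lenses1: LensSet,
    lenses2: LensSet,
    mode: str | None = None,
    compute_objective: bool = True,
) -> PolarizationDecomposition:
    """Decompose perceived polarization between two waves.

    ``P1 = dbar(X2, L1) - dbar(X1, L1)`` (opinions change, lenses frozen),
    ``P2 = dbar(X2, L2) - dbar(X2, L1)`` (lenses update on fixed opinions),
    ``P = dbar(X2, L2) - dbar(X1, L1) = P1 + P2``. Perceivers in one wave
    whose group has no lens in the other wave's set use that set's
    population lens (logged). Per-group triples restrict the perceiving
    side; groups must appear in both waves to get a triple.
    """
    if list(wave1.item_names) != list(wave2.item_names):
        raise ValueError(
            f"waves disagree on items: {wave1.item_names} vs {wave2.item_names}"
        )
    fixed = lenses2 is lenses1 or lenses2 == lenses1
    if mode is None:
        mode = "fixed" if fixed else "custom"

    d11 = mean_disagreement(wave1, lenses1, compute_objective=compute_objective)
    d21 = mean_disagreement(wave2, lenses1, compute_objective=compute_objective)
    d22 = d21 if fixed else mean_disagreement(
        wave2, lenses2, compute_objective=compute_objective
    )

    p1 = d21.population_mean - d11.population_mean
    p2 = d22.population_mean - d21.population_mean
    p = d22.population_mean - d11.population_mean
    p_obj = d22.objective_mean - d11.objective_mean

    per_group: dict[str, dict[str, float]] = {}
    per_group_rel: dict[str, dict[str, float]] = {}
    shared = [g for g in wave2.groups() if g in set(wave1.groups())]
    for g in shared:
        g11 = d11.per_group_mean[g]
        g21 = d21.per_group_mean[g]
        g22 = d22.per_group_mean[g]
        triple = {"P": g22 - g11, "P1": g21 - g11, "P2": g22 - g21}
        per_group[g] = triple
        per_group_rel[g] = {q: v / g11 for q, v in triple.items()}

    base = d11.population_mean
    return PolarizationDecomposition(
        t1=wave1.wave_label,
        t2=wave2.wave_label,
        P=p,
        P1=p1,
        P2=p2,
        P_objective=p_obj,
        mode=mode,
        per_group=per_group,
        relative={"P": p / base, "P1": p1 / base, "P2": p2 / base},
        per_group_relative=per_group_rel,
        baseline=d11,
        cross=d21,
        final=d22,
    )


def decompose_instantaneous(
    wave1: OpinionWave,
    wave2: OpinionWave,
    ridge_epsilon: float = 1e-6,
    min_group_size: int = 3,
    compute_objective: bool = True,
) -> PolarizationDecomposition:
    """Decomposition with lenses refitted to each wave (zero updating delay).

    Fits the lens sets on ``wave1`` and ``wave2`` internally; the returned
    ``P2`` field carries the instantaneous lens-specific polarization P2*.
    """
    lenses1 = build_lens_set(wave1, ridge_epsilon, min_group_size)
    lenses2 = build_lens_set(wave2, ridge_epsilon, min_group_size)
    return decompose(
        wave1, wave2, lenses1, lenses2,
        mode="instantaneous", compute_objective=compute_objective,
    )
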