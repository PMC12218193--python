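"""Group-structured synthetic opinion waves.

Emulates the statistical structure the analysis assumes: several identity
groups, each a (truncated) Gaussian cloud in the bounded opinion space
[0, 1]^m with its own mean and covariance, wave-to-wave changes in those
moments (contraction / expansion / rotation), optional snapping to a Likert
grid, and per-respondent analysis weights. Waves within a scenario share the
underlying standard-normal draws (common random numbers), so a wave that
differs from another only by a covariance factor is the literal point-wise
contraction of it — unchanged groups carry identical points.

Sampling is truncated-Gaussian by rejection (resample-until-inside) rather
than clipping, to avoid boundary atoms that would distort covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .opinion_model import NONPARTISAN_LABEL, LikertScheme, OpinionWave

__all__ = [
    "GroupSpec",
    "ScenarioSpec",
    "contraction_scenario",
    "discretize_to_likert",
    "generate_scenario",
    "generate_wave",
    "two_lenses_scenario",
]

_MAX_RESAMPLE = 1000  # retry budget per point for the rejection sampler


@dataclass(frozen=True)
class GroupSpec:
    """One identity group's generative law for a single wave."""

    label: str
    n: int
    mean: tuple[float, ...]
    covariance: np.ndarray
    weight_value: float = 1.0  # constant analysis weight
    weight_jitter: float = 0.0  # lognormal sigma; 0 = constant weights

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if np.max(np.abs(cov - cov.T)) > 1e-10:
            raise ValueError(f"group {self.label!r}: covariance not symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError(f"group {self.label!r}: covariance not PSD")
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "mean", tuple(float(v) for v in self.mean))
        if len(self.mean) != cov.shape[0]:
            raise ValueError(f"group {self.label!r}: mean/covariance dimension mismatch")


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered list of waves, each a list of :class:`GroupSpec`."""

    waves: tuple[tuple[str, tuple[GroupSpec, ...]], ...]
    seed: int = 0
    item_names: tuple[str, ...] | None = None
    discretize: LikertScheme | None = None
    shared_draws: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "waves", tuple((wl, tuple(specs)) for wl, specs in self.waves)
        )
        labels0 = [g.label for g in self.waves[0][1]]
        m0 = len(self.waves[0][1][0].mean)
        for wl, specs in self.waves:
            labels = [g.label for g in specs]
            if labels != labels0:
                raise ValueError(
                    f"wave {wl!r} group labels {labels} differ from {labels0}"
                )
            for g in specs:
                if len(g.mean) != m0:
                    raise ValueError(f"wave {wl!r}: inconsistent dimension")

    @property
    def m(self) -> int:
        return len(self.waves[0][1][0].mean)


def _sqrt_psd(cov: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(np.asarray(cov, dtype=float))
    return evecs * np.sqrt(np.clip(evals, 0.0, None))[None, :]


def _sample_group(spec: GroupSpec, z: np.ndarray, rng: np.random.Generator):
    """Map standard-normal draws through the group's law; reject-and-resample
    points falling outside [0, 1]^m."""
    root = _sqrt_psd(spec.covariance)
    x = np.asarray(spec.mean) + z @ root.T
    outside = np.any((x < 0.0) | (x > 1.0), axis=1)
    tries = 0
    while outside.any():
        tries += 1
        if tries > _MAX_RESAMPLE:
            raise RuntimeError(
                f"group {spec.label!r}: truncation to [0,1]^m rejected draws "
                f"{_MAX_RESAMPLE} times; acceptance probability too low"
            )
        k = int(outside.sum())
        x[outside] = np.asarray(spec.mean) + rng.standard_normal((k, z.shape[1])) @ root.T
        outside = np.any((x < 0.0) | (x > 1.0), axis=1)
    return x


def generate_wave(
    specs,
    seed: int,
    wave_label: str = "w1",
    item_names=None,
) -> OpinionWave:
    """Draw one wave from a list of :class:`GroupSpec`.

    Reproducible for a given seed. Each group consumes its own random
    stream seeded by ``(seed, group position)``, so two waves generated
    with the same seed share their underlying draws group by group
    (common random numbers): a group whose spec is unchanged between the
    waves reproduces the identical points, and one whose covariance is
    scaled yields the point-wise rescaled cloud.
    """
    xs, labels, weights = [], [], []
    m = len(specs[0].mean)
    for gi, spec in enumerate(specs):
        rng = np.random.default_rng([int(seed) % 2**31, gi])
        z = rng.standard_normal((spec.n, m))
        xs.append(_sample_group(spec, z, rng))
        labels.extend([spec.label] * spec.n)
        w = np.full(spec.n, float(spec.weight_value))
        if spec.weight_jitter > 0:
            w = w * rng.lognormal(mean=0.0, sigma=spec.weight_jitter, size=spec.n)
        weights.append(w)
    if item_names is None:
        item_names = [f"item_{j+1}" for j in range(m)]
    return OpinionWave(
        wave_label=wave_label,
        opinions=np.vstack(xs),
        identities=labels,
        weights=np.concatenate(weights),
        item_names=list(item_names),
    )


def generate_scenario(scenario: ScenarioSpec) -> list[OpinionWave]:
    """Generate every wave of a scenario.

    With ``shared_draws`` (the default) all waves use the same seed, so
    groups with unchanged specs carry identical points across waves and a
    covariance contraction becomes the literal point-wise contraction.
    Without it, each wave is an independent cross-section.
    """
    waves = []
    for k, (wave_label, specs) in enumerate(scenario.waves):
        seed = scenario.seed if scenario.shared_draws else scenario.seed + 7919 * (k + 1)
        waves.append(
            generate_wave(
                list(specs),
                seed=seed,
                wave_label=wave_label,
                item_names=scenario.item_names,
            )
        )
    return waves


def contraction_scenario(
    base: ScenarioSpec, group_label: str, factor: float
) -> ScenarioSpec:
    """Two-wave scenario in which one group's opinion distribution contracts.

    Wave 2 equals wave 1 except the named group's covariance is multiplied
    by ``factor**2`` (standard deviations by ``factor``), draws re-centered
    on the same mean via common random numbers. The contracting group's lens
    narrows, so under instantaneous lens updating its perceived distances to
    everyone grow by ~1/factor (positive P2*), while observers with fixed
    lenses see essentially unchanged disagreement.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    wave_label, specs = base.waves[0]
    if group_label not in [g.label for g in specs]:
        raise ValueError(f"group {group_label!r} not in scenario")
    contracted = tuple(
        replace(g, covariance=g.covariance * factor**2) if g.label == group_label else g
        for g in specs
    )
    return replace(base, waves=((wave_label, specs), (wave_label + "_contracted", contracted)))


def two_lenses_scenario(
    n_per_group: int = 2000, seed: int = 0, m: int = 2
) -> ScenarioSpec:
    """Default two-group fixture: a tight "red" cloud and a wide,
    anisotropic "blue" cloud.

    The homogeneous red group's narrow lens makes it perceive the opinion
    gap to blue as large, while the heterogeneous blue group perceives the
    same gap as small — the asymmetric-perception construction.
    """
    if m != 2:
        raise ValueError("the two-lenses fixture is two-dimensional")
    red = GroupSpec(
        label="red", n=n_per_group, mean=(0.3, 0.35),
        covariance=np.diag([0.05**2, 0.05**2]),
    )
    blue = GroupSpec(
        label="blue", n=n_per_group, mean=(0.72, 0.68),
        covariance=np.diag([0.15**2, 0.11**2]),
    )
    return ScenarioSpec(waves=(("w1", (red, blue)),), seed=seed)


def discretize_to_likert(wave: OpinionWave, scheme: LikertScheme) -> pd.DataFrame:
    """Snap opinions to the nearest Likert level and emit a survey table.

    Columns: ``wave``, ``identity``, ``weight`` and one ordinal-coded column
    per item — the layout ``survey_io`` reads, enabling end-to-end tests.
    """
    unit_vals = np.asarray(scheme.unit_values)
    codes = np.asarray(scheme.levels)[
        np.argmin(np.abs(wave.opinions[..., None] - unit_vals[None, None, :]), axis=2)
    ]
    df = pd.DataFrame(
        {
            "wave": wave.wave_label,
            "identity": wave.identities,
            "weight": wave.weights,
        }
    )
    for j, name in enumerate(wave.item_names):
        df[name] = codes[:, j]
    return df
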