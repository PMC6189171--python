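"""Contact mechanics and nonparametric statistics for phagocytosis assays.

Covers four measurements:

* the Hertz model for a rigid spherical indenter on an elastic half-space,
  F = (4/3) (E / (1 - nu^2)) sqrt(R) delta^(3/2), and least-squares
  estimation of the Young's modulus E (and contact-point offset delta0)
  from force–indentation curves;
* the exact-permutation Spearman rank test used to relate target stiffness
  to phagocytic efficiency at small group counts (full enumeration of the
  n! rank permutations for n <= 9);
* internalized volume/surface totals for spherical beads,
  V = (4/3) pi r^3 and S = 4 pi r^2 per bead;
* phagocytosis-efficiency summaries from per-cell internalized/surface
  bead counts (the fluorescence-exclusion labeling assay distinguishes the
  two classes; both the responding-cell fraction and the mean bead count
  are reported).

SI units are used internally; the TSV I/O boundary accepts nm and nN and
converts explicitly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HertzParams:
    """Hertz-model parameters in SI units."""

    E: float  # Young's modulus, Pa
    nu: float = 0.33  # Poisson ratio
    R: float = 1.5e-6  # effective indenter radius, m
    delta0: float = 0.0  # contact-point offset, m

    def __post_init__(self):
        if not self.E > 0:
            raise ValueError("Young's modulus must be positive")
        if not (0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if not self.R > 0:
            raise ValueError("probe radius must be positive")


@dataclass
class ForceCurve:
    """Indentation (m) / force (N) samples plus probe geometry."""

    delta: np.ndarray
    force: np.ndarray
    R: float
    nu: float = 0.33

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.delta.shape != self.force.shape:
            raise ValueError("delta and force must have equal length")
        if not np.isfinite(self.force).all():
            raise ValueError("forces must be finite")

    @classmethod
    def from_nm_nN(cls, delta_nm, force_nN, R_nm: float, nu: float = 0.33) -> "ForceCurve":
        log.info("converting curve units: nm -> m, nN -> N (R = %g nm)", R_nm)
        return cls(
            delta=np.asarray(delta_nm, float) * 1e-9,
            force=np.asarray(force_nN, float) * 1e-9,
            R=R_nm * 1e-9,
            nu=nu,
        )


def hertz_force(delta, params: HertzParams):
    """Hertz contact force F = (4/3)(E/(1-nu^2)) sqrt(R) delta^(3/2), in N."""
    delta = np.asarray(delta, dtype=float)
    if (delta < 0).any():
        raise ValueError("indentation must be nonnegative")
    k = (4.0 / 3.0) * params.E / (1.0 - params.nu**2) * math.sqrt(params.R)
    return k * delta**1.5


@dataclass
class HertzFit:
    params: HertzParams
    residual_rms: float  # N


def fit_hertz(curve: ForceCurve, fix_delta0: float | None = None) -> HertzFit:
    """Least-squares Hertz fit of (E, delta0) to a force curve.

    The model is F = (4/3)(E/(1-nu^2)) sqrt(R) max(delta - delta0, 0)^(3/2);
    delta0 can be pinned with ``fix_delta0``.  Requires >= 10 samples with
    positive indentation.  A nonpositive fitted E or failed convergence is
    an error.
    """
    if (curve.delta[curve.delta > 0]).size < 10:
        raise ValueError("need >= 10 post-contact samples to fit")
    pref = (4.0 / 3.0) / (1.0 - curve.nu**2) * math.sqrt(curve.R)

    def model(x):
        E, d0 = x
        return pref * E * np.clip(curve.delta - d0, 0.0, None) ** 1.5

    if fix_delta0 is not None:
        phi = pref * np.clip(curve.delta - fix_delta0, 0.0, None) ** 1.5
        denom = float(phi @ phi)
        if denom == 0:
            raise ValueError("no positive indentation beyond fixed delta0")
        E = float(phi @ curve.force) / denom
        if E <= 0:
            raise ValueError(f"fitted Young's modulus is nonpositive ({E:.3g} Pa)")
        resid = curve.force - phi * E
        return HertzFit(
            HertzParams(E=E, nu=curve.nu, R=curve.R, delta0=fix_delta0),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )

    # the problem is linear in E at fixed delta0, so profile E in closed form
    # over a delta0 grid to find the global basin before the joint refine
    span = float(curve.delta.max())
    best = None
    for d0 in np.linspace(-0.3 * span, 0.7 * span, 61):
        phi = pref * np.clip(curve.delta - d0, 0.0, None) ** 1.5
        denom = float(phi @ phi)
        if denom == 0:
            continue
        E_hat = float(phi @ curve.force) / denom
        sse = float(np.sum((curve.force - phi * E_hat) ** 2))
        if best is None or sse < best[0]:
            best = (sse, E_hat, d0)
    if best is None:
        raise ValueError("no positive indentation in curve")
    _, E0, d0_init = best
    E0 = max(E0, 1.0)

    res = optimize.least_squares(
        lambda x: model(x) - curve.force,
        x0=[E0, d0_init],
        bounds=([0.0, -0.5 * span], [np.inf, 0.9 * span]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"Hertz fit did not converge: {res.message}")
    E, d0 = res.x
    if E <= 0:
        raise ValueError(f"fitted Young's modulus is nonpositive ({E:.3g} Pa)")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return HertzFit(HertzParams(E=float(E), nu=curve.nu, R=curve.R, delta0=float(d0)), rms)


@dataclass
class SpearmanResult:
    r: float
    p_one_sided: float
    p_two_sided: float
    n: int
    rank_differences: np.ndarray = field(repr=False, default=None)
    exact: bool = True


def _spearman_r(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    rx = rank_x - rank_x.mean()
    ry = rank_y - rank_y.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_exact(x, y, max_exact_n: int = 9) -> SpearmanResult:
    """Spearman rank correlation with an exact permutation p-value.

    For untied data r = 1 - 6 sum(d_i^2) / (n (n^2 - 1)).  The one-sided
    p-value is the exact upper-tail probability P(statistic >= observed)
    over all n! equally likely permutations of the y-ranks (full enumeration
    for n <= ``max_exact_n``); the two-sided value doubles the smaller tail,
    capped at 1.  Ties are handled with midranks for r, but an exact p with
    ties is refused — use the large-sample approximation instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    tied = len(set(rank_x)) < n or len(set(rank_y)) < n
    r = _spearman_r(rank_x, rank_y)
    d = rank_x - rank_y

    if n <= max_exact_n:
        if tied:
            raise ValueError(
                "exact permutation p undefined with ties; use the t approximation "
                "(pass max_exact_n=0)"
            )
        # the null distribution is invariant to the x ordering for untied
        # ranks, so enumerate y-rank permutations against the identity
        upper = lower = 0
        total = 0
        rx = np.arange(1.0, n + 1.0)
        tol = 1e-12
        for perm in itertools.permutations(range(n)):
            ry = np.asarray(perm, dtype=float) + 1.0
            stat = _spearman_r(rx, ry)
            if stat >= r - tol:
                upper += 1
            if stat <= r + tol:
                lower += 1
            total += 1
        p_one = upper / total
        p_two = min(1.0, 2.0 * min(upper, lower) / total)
        return SpearmanResult(r, p_one, p_two, n, d, exact=True)

    # large-sample t approximation
    log.info("n = %d > %d: using t approximation for Spearman p", n, max_exact_n)
    t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    p_upper = float(stats.t.sf(t, df=n - 2))
    p_two = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(r, p_upper, min(1.0, p_two), n, d, exact=False)


def internalized_geometry(bead_diameter_um: float, beads_per_cell: float) -> tuple[float, float]:
    """Per-cell internalized (volume um^3, surface um^2) for spherical beads.

    V = count x (4/3) pi r^3 and S = count x 4 pi r^2 with r = diameter/2.
    """
    if bead_diameter_um <= 0:
        raise ValueError("bead diameter must be positive")
    if beads_per_cell < 0:
        raise ValueError("bead count must be nonnegative")
    r = bead_diameter_um / 2.0
    return (
        beads_per_cell * (4.0 / 3.0) * math.pi * r**3,
        beads_per_cell * 4.0 * math.pi * r**2,
    )


@dataclass
class PhagocytosisSummary:
    fraction_positive: float  # cells with >= 1 internalized bead
    mean_internalized: float  # beads per cell
    distribution: dict[int, int]  # internalized count -> number of cells
    mean_surface_bound: float | None = None


def phagocytosis_efficiency(
    internalized: np.ndarray, surface_bound: np.ndarray | None = None
) -> PhagocytosisSummary:
    """Summaries of per-cell internalized bead counts.

    The assay labels only uninternalized beads, so internalized counts are
    direct readouts.  Both candidate "efficiency" definitions are reported:
    the fraction of cells with at least one internalized bead, and the mean
    internalized bead count per cell.
    """
    internalized = np.asarray(internalized)
    if internalized.size == 0:
        raise ValueError("empty cell list")
    if (internalized < 0).any():
        raise ValueError("counts must be nonnegative")
    values, counts = np.unique(internalized, return_counts=True)
    mean_surface = None
    if surface_bound is not None:
        surface_bound = np.asarray(surface_bound)
        if surface_bound.shape != internalized.shape:
            raise ValueError("surface-bound counts must match cell list length")
        mean_surface = float(surface_bound.mean())
    return PhagocytosisSummary(
        fraction_positive=float((internalized >= 1).mean()),
        mean_internalized=float(internalized.mean()),
        distribution={int(v): int(c) for v, c in zip(values, counts)},
        mean_surface_bound=mean_surface,
    )
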