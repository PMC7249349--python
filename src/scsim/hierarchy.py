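"""Truncated hierarchical Dirichlet sampling of genotype proportions.

The grouped sampling design is modelled by three nested Dirichlet draws
over the K prototype genomes::

    G''    ~ Dirichlet(alpha)                 (population)
    G'_i   ~ Dirichlet(beta_i  * G'')         (biological unit i)
    G_ij   ~ Dirichlet(gamma_ij * G'_i)       (sample j of unit i)

Small concentration parameters (beta_i, gamma_ij ~ 0.1) produce draws
concentrated near a single vertex of the simplex — a sample dominated by
one genotype — while large values shrink each level onto its parent.  As
K grows with genotypes drawn i.i.d. from a base measure the model
approaches a hierarchical Dirichlet process mixture; with a fixed K it is
the truncated analogue used here.

Numerics: child concentrations ``beta_i * G''_k`` can be astronomically
small, so draws use log-gamma variates (``scipy.stats.loggamma``) and a
log-sum-exp normalization rather than raw gamma variates, which would
underflow to an all-zero vector.  Concentrations are floored at 1e-12
before drawing, and simplex entries below 1e-12 are clamped and the
vector renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import ExperimentDesign
from .errors import RangeError
from .rng import child_seed, rng_for

__all__ = ["HierarchyDraw", "sample_dirichlet", "sample_hierarchy"]

_CONC_FLOOR = 1e-12
_SIMPLEX_FLOOR = 1e-12


@dataclass(frozen=True)
class HierarchyDraw:
    """Realized simplex vectors at all three levels of the hierarchy."""

    g_pop: np.ndarray                          # length K
    g_unit: dict[str, np.ndarray]              # unit id -> length K
    g_sample: dict[tuple[str, str], np.ndarray]  # (unit id, sample id) -> length K

    def to_jsonable(self) -> dict:
        return {
            "g_pop": self.g_pop.tolist(),
            "g_unit": {u: v.tolist() for u, v in self.g_unit.items()},
            "g_sample": {f"{u}/{s}": v.tolist()
                         for (u, s), v in self.g_sample.items()},
        }


def sample_dirichlet(concentration, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet draw robust to very small concentration parameters.

    Uses normalized log-gamma variates so that concentrations down to the
    1e-12 floor still yield a well-defined draw (essentially one-hot at a
    component chosen with probability proportional to its concentration).
    """
    conc = np.asarray(concentration, dtype=float)
    if conc.ndim != 1 or conc.size == 0:
        raise RangeError("concentration must be a non-empty 1-D vector")
    if np.any(conc < 0):
        raise RangeError("concentration entries must be non-negative")
    if not np.any(conc > 0):
        raise RangeError("degenerate Dirichlet parameter: all entries zero")
    conc = np.maximum(conc, _CONC_FLOOR)
    if conc.size == 1:
        return np.ones(1)
    log_g = stats.loggamma.rvs(conc, random_state=rng)
    log_g -= log_g.max()
    x = np.exp(log_g)
    x /= x.sum()
    x = np.maximum(x, _SIMPLEX_FLOOR)
    return x / x.sum()


def sample_hierarchy(design: ExperimentDesign, seed: int | None = None) -> HierarchyDraw:
    """Draw the full hierarchy for a design: one G'', per-unit G'_i, per-sample G_ij.

    Each vector gets its own child seed keyed by stage and unit/sample id,
    so adding a sample to the design leaves all other draws unchanged.
    G'' is drawn once per run.
    """
    master = design.seed if seed is None else seed
    g_pop = sample_dirichlet(np.asarray(design.alpha), rng_for(master, "hierarchy", "pop"))
    g_unit: dict[str, np.ndarray] = {}
    g_sample: dict[tuple[str, str], np.ndarray] = {}
    for unit in design.units:
        g_unit[unit.id] = sample_dirichlet(
            unit.beta * g_pop, rng_for(master, "hierarchy", "unit", unit.id))
        for s in unit.samples:
            g_sample[(unit.id, s.id)] = sample_dirichlet(
                s.gamma * g_unit[unit.id],
                rng_for(master, "hierarchy", "sample", unit.id, s.id))
    return HierarchyDraw(g_pop=g_pop, g_unit=g_unit, g_sample=g_sample)


def hierarchy_child_seeds(design: ExperimentDesign, seed: int | None = None) -> dict:
    """The child seeds used by :func:`sample_hierarchy` (for the manifest)."""
    master = design.seed if seed is None else seed
    seeds = {"pop": child_seed(master, "hierarchy", "pop")}
    for unit in design.units:
        seeds[f"unit/{unit.id}"] = child_seed(master, "hierarchy", "unit", unit.id)
        for s in unit.samples:
            seeds[f"sample/{unit.id}/{s.id}"] = child_seed(
                master, "hierarchy", "sample", unit.id, s.id)
    return seeds
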