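"""Experiment-design parsing and validation.

The simulator is driven by a YAML document describing the sampling design:
a grouped hierarchy of biological units (e.g. patients) each holding bulk
and/or single-cell samples, the number of mutated prototype genomes ``K``,
the number of potential SNV locations ``n_snv``, the Dirichlet concentration
parameters (population-level ``alpha``, per-unit ``beta``, per-sample
``gamma``), whole-genome-amplification error rates, and read-simulation
parameters.

Schema (keys)::

    reference: optional path to the reference FASTA
    region: {start: int, length: int}
    prototypes:
      K: int
      n_snv: int
      margin_fraction: float          # default 0.1
      substitution:                   # all optional
        p_het: float                  # default 0.5
        transition_prob: float        # default 0.58; builds the matrix
        matrix: 4x4 row-stochastic    # overrides transition_prob
        tier_fractions: [f,f,f]       # default [1/3,1/3,1/3]
    alpha: [a_1, ..., a_K]
    units:
      - id: str
        beta: float
        samples:
          - {id, type: bulk|single_cell, gamma, coverage, n_bulk_reads}
    wga: {ado_rate: float, fp_rate: float}
    reads: {length, fragment_mean, fragment_sd, error_rate, base_quality}
    seed: int
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, DimensionError, RangeError

__all__ = [
    "SampleType",
    "SampleSpec",
    "BiologicalUnitSpec",
    "WgaParams",
    "ReadParams",
    "SnvModelParams",
    "ExperimentDesign",
    "load_design",
    "serialize_design",
    "default_subst_matrix",
    "BASES",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Transitions are A<->G and C<->T.
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def default_subst_matrix(transition_prob: float = 0.58) -> np.ndarray:
    """4x4 row-stochastic substitution matrix (rows/cols in A,C,G,T order).

    Each row puts ``transition_prob`` mass on the transition partner of the
    reference base and splits the remainder equally over the two
    transversions; the diagonal is zero.  The default 0.58 yields a
    transition/transversion ratio of 0.58/0.42 ~ 1.38, inside the 1.2-1.6
    band typical of human SNV sets.
    """
    if not 0.0 <= transition_prob <= 1.0:
        raise RangeError(f"transition_prob must be in [0,1], got {transition_prob}")
    tv = (1.0 - transition_prob) / 2.0
    m = np.zeros((4, 4))
    for ref in BASES:
        i = _BASE_INDEX[ref]
        for alt in BASES:
            if alt == ref:
                continue
            j = _BASE_INDEX[alt]
            m[i, j] = transition_prob if alt == _TRANSITION_PARTNER[ref] else tv
    return m


class SampleType(str, enum.Enum):
    BULK = "bulk"
    SINGLE_CELL = "single_cell"


@dataclass(frozen=True)
class SampleSpec:
    id: str
    type: SampleType
    gamma: float
    coverage: float
    n_bulk_reads: int | None = None

    def __post_init__(self):
        if self.gamma <= 0:
            raise RangeError(f"sample {self.id!r}: gamma must be > 0, got {self.gamma}")
        if self.coverage <= 0:
            raise RangeError(
                f"sample {self.id!r}: coverage must be > 0, got {self.coverage}"
            )
        if self.type is SampleType.BULK:
            if self.n_bulk_reads is None:
                raise ConfigurationError(
                    f"sample {self.id!r}: bulk samples require n_bulk_reads"
                )
            if self.n_bulk_reads < 0:
                raise RangeError(
                    f"sample {self.id!r}: n_bulk_reads must be >= 0"
                )
        elif self.n_bulk_reads is not None:
            raise ConfigurationError(
                f"sample {self.id!r}: n_bulk_reads only applies to bulk samples"
            )


@dataclass(frozen=True)
class BiologicalUnitSpec:
    id: str
    beta: float
    samples: tuple[SampleSpec, ...]

    def __post_init__(self):
        if self.beta <= 0:
            raise RangeError(f"unit {self.id!r}: beta must be > 0, got {self.beta}")
        if not self.samples:
            raise ConfigurationError(f"unit {self.id!r}: at least one sample required")


@dataclass(frozen=True)
class WgaParams:
    """Whole-genome-amplification error model parameters.

    ``ado_rate`` is the per-heterozygous-site probability of allelic
    dropout; ``fp_rate`` is the per-base probability of a spurious
    (false-positive) heterozygous mutation over the whole region.
    """

    ado_rate: float = 0.20
    fp_rate: float = 3.2e-5

    def __post_init__(self):
        for name in ("ado_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise RangeError(f"wga.{name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class ReadParams:
    """Parameters of the internal paired-end read engine."""

    read_length: int = 100
    fragment_mean: float = 500.0
    fragment_sd: float = 50.0
    error_rate: float = 0.001
    base_quality: int = 30

    def __post_init__(self):
        if self.read_length < 1:
            raise RangeError("reads.length must be >= 1")
        if self.fragment_mean < 2 * self.read_length:
            raise RangeError(
                "reads.fragment_mean must be >= 2 * read_length "
                f"({self.fragment_mean} < {2 * self.read_length})"
            )
        if not 0.0 <= self.error_rate < 1.0:
            raise RangeError("reads.error_rate must be in [0,1)")


@dataclass(frozen=True)
class SnvModelParams:
    """SNV placement/typing model: tier fractions, zygosity, substitutions."""

    tier_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    p_het: float = 0.5
    subst_matrix: np.ndarray = field(default_factory=default_subst_matrix)

    def __post_init__(self):
        m = np.asarray(self.subst_matrix, dtype=float)
        if m.shape != (4, 4):
            raise DimensionError(f"subst_matrix must be 4x4, got {m.shape}")
        if np.any(np.diag(m) != 0):
            raise ConfigurationError("subst_matrix diagonal must be zero")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError(
                "each subst_matrix row must be non-negative and sum to 1 within 1e-9"
            )
        object.__setattr__(self, "subst_matrix", m)
        tf = tuple(float(x) for x in self.tier_fractions)
        if len(tf) != 3 or abs(sum(tf) - 1.0) > 1e-9 or any(x < 0 for x in tf):
            raise ConfigurationError("tier_fractions must be 3 proportions summing to 1")
        object.__setattr__(self, "tier_fractions", tf)
        if not 0.0 <= self.p_het <= 1.0:
            raise RangeError(f"p_het must be in [0,1], got {self.p_het}")


@dataclass(frozen=True)
class ExperimentDesign:
    region_start: int
    region_length: int
    K: int
    n_snv: int
    alpha: tuple[float, ...]
    units: tuple[BiologicalUnitSpec, ...]
    wga: WgaParams = WgaParams()
    reads: ReadParams = ReadParams()
    subst: SnvModelParams = SnvModelParams()
    margin_fraction: float = 0.1
    seed: int = 0
    reference: str | None = None

    def __post_init__(self):
        if self.K < 1:
            raise RangeError(f"K must be >= 1, got {self.K}")
        if self.n_snv < 1:
            raise RangeError(f"n_snv must be >= 1, got {self.n_snv}")
        alpha = tuple(float(a) for a in self.alpha)
        if len(alpha) != self.K:
            raise DimensionError(
                f"alpha must have length K={self.K}, got {len(alpha)}"
            )
        if any(a <= 0 for a in alpha):
            raise RangeError("every alpha entry must be > 0")
        object.__setattr__(self, "alpha", alpha)
        if self.region_length < 2 * self.n_snv:
            raise RangeError(
                f"region length {self.region_length} too small for "
                f"{self.n_snv} distinct SNV positions (need >= {2 * self.n_snv})"
            )
        if self.region_start < 0:
            raise RangeError("region.start must be >= 0")
        if not 0.0 <= self.margin_fraction < 0.5:
            raise RangeError("margin_fraction must be in [0, 0.5)")
        if not self.units:
            raise ConfigurationError("no biological units in design")
        ids = [s.id for u in self.units for s in u.samples] + [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("unit and sample ids must be unique")

    @property
    def samples(self) -> list[tuple[BiologicalUnitSpec, SampleSpec]]:
        return [(u, s) for u in self.units for s in u.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _require(mapping: dict, key: str, where: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ConfigurationError(f"missing required field {where}.{key}"
                                 if where else f"missing required field {key}")
    return mapping[key]


def load_design(yaml_text: str) -> ExperimentDesign:
    """Parse a YAML experiment design and validate all invariants.

    Optional fields receive their documented defaults (e.g. ado_rate=0.2,
    fp_rate=3.2e-5).  Raises :class:`ConfigurationError` naming the missing
    field, :class:`DimensionError` on shape mismatches, or
    :class:`RangeError` on out-of-range values.
    """
    doc = yaml.safe_load(yaml_text)
    if not isinstance(doc, dict):
        raise ConfigurationError("design YAML must be a mapping at top level")

    region = _require(doc, "region", "")
    protos = _require(doc, "prototypes", "")
    sub_cfg = protos.get("substitution") or {}
    if "matrix" in sub_cfg:
        matrix = np.asarray(sub_cfg["matrix"], dtype=float)
    else:
        matrix = default_subst_matrix(float(sub_cfg.get("transition_prob", 0.58)))
    subst = SnvModelParams(
        tier_fractions=tuple(sub_cfg.get("tier_fractions", (1 / 3, 1 / 3, 1 / 3))),
        p_het=float(sub_cfg.get("p_het", 0.5)),
        subst_matrix=matrix,
    )

    units = []
    for u in _require(doc, "units", ""):
        samples = []
        for s in _require(u, "samples", "units[]"):
            stype_raw = _require(s, "type", "units[].samples[]")
            try:
                stype = SampleType(stype_raw)
            except ValueError:
                raise ConfigurationError(
                    f"sample type must be 'bulk' or 'single_cell', got {stype_raw!r}"
                ) from None
            samples.append(
                SampleSpec(
                    id=str(_require(s, "id", "units[].samples[]")),
                    type=stype,
                    gamma=float(_require(s, "gamma", "units[].samples[]")),
                    coverage=float(s.get("coverage", doc.get("coverage", 24.0))),
                    n_bulk_reads=(int(s["n_bulk_reads"])
                                  if s.get("n_bulk_reads") is not None else None),
                )
            )
        units.append(
            BiologicalUnitSpec(
                id=str(_require(u, "id", "units[]")),
                beta=float(_require(u, "beta", "units[]")),
                samples=tuple(samples),
            )
        )

    wga_cfg = doc.get("wga") or {}
    reads_cfg = doc.get("reads") or {}
    return ExperimentDesign(
        region_start=int(_require(region, "start", "region")),
        region_length=int(_require(region, "length", "region")),
        K=int(_require(protos, "K", "prototypes")),
        n_snv=int(_require(protos, "n_snv", "prototypes")),
        margin_fraction=float(protos.get("margin_fraction", 0.1)),
        alpha=tuple(float(a) for a in _require(doc, "alpha", "")),
        units=tuple(units),
        wga=WgaParams(
            ado_rate=float(wga_cfg.get("ado_rate", 0.20)),
            fp_rate=float(wga_cfg.get("fp_rate", 3.2e-5)),
        ),
        reads=ReadParams(
            read_length=int(reads_cfg.get("length", 100)),
            fragment_mean=float(reads_cfg.get("fragment_mean", 500.0)),
            fragment_sd=float(reads_cfg.get("fragment_sd", 50.0)),
            error_rate=float(reads_cfg.get("error_rate", 0.001)),
            base_quality=int(reads_cfg.get("base_quality", 30)),
        ),
        subst=subst,
        seed=int(doc.get("seed", 0)),
        reference=doc.get("reference"),
    )


def serialize_design(design: ExperimentDesign) -> str:
    """YAML text that :func:`load_design` parses back to an equal design."""
    doc = {
        "reference": design.reference,
        "region": {"start": design.region_start, "length": design.region_length},
        "prototypes": {
            "K": design.K,
            "n_snv": design.n_snv,
            "margin_fraction": design.margin_fraction,
            "substitution": {
                "p_het": design.subst.p_het,
                "tier_fractions": list(design.subst.tier_fractions),
                "matrix": design.subst.subst_matrix.tolist(),
            },
        },
        "alpha": list(design.alpha),
        "units": [
            {
                "id": u.id,
                "beta": u.beta,
                "samples": [
                    {k: v for k, v in {
                        "id": s.id,
                        "type": s.type.value,
                        "gamma": s.gamma,
                        "coverage": s.coverage,
                        "n_bulk_reads": s.n_bulk_reads,
                    }.items() if v is not None}
                    for s in u.samples
                ],
            }
            for u in design.units
        ],
        "wga": dataclasses.asdict(design.wga),
        "reads": {
            "length": design.reads.read_length,
            "fragment_mean": design.reads.fragment_mean,
            "fragment_sd": design.reads.fragment_sd,
            "error_rate": design.reads.error_rate,
            "base_quality": design.reads.base_quality,
        },
        "seed": design.seed,
    }
    if design.reference is None:
        del doc["reference"]
    return yaml.safe_dump(doc, sort_keys=False)
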