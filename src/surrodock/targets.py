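"""Regression targets: energy summary statistics and binding affinity.

A docking run produces, per iteration, 13 interaction-energy terms
(complex energy minus isolated protein and ligand energies). The
surrogate is trained to predict 7 summary statistics of each term —
mean, median, standard deviation, minimum, maximum, skewness and excess
kurtosis — plus the binding affinity pK = -log10(K / 1 M), a 92-long
target vector. Moments use the population (divisor-n) convention; when a
term is constant across iterations its std, skew and kurtosis are 0 so
single-iteration runs stay usable.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_TERM_NAMES",
    "STAT_NAMES",
    "REQUIRED_TERM",
    "EnergySamples",
    "SummaryTargets",
    "interaction_energy",
    "summarize_samples",
    "summarize_energies",
    "pk_from_constant",
    "constant_from_pk",
    "read_docking_table",
    "read_affinity_table",
    "N_TERMS",
    "N_STATS",
    "TARGET_LENGTH",
]

REQUIRED_TERM = "E_without_VDWR"

#: default 13-term set: the affinity-relevant E_without_VDWR plus 12
#: force-field-style components (the last five are typically inactive)
DEFAULT_TERM_NAMES = (
    "E_without_VDWR",
    "E_total",
    "E_VDW_attr",
    "E_VDW_rep",
    "E_solvation",
    "E_HB_bb_sc",
    "E_HB_sc_sc",
    "E_elec",
    "E_HB_bb_bb",
    "E_torsion",
    "E_aromatic",
    "E_pi_stack",
    "E_cation_pi",
)

STAT_NAMES = ("mean", "median", "std", "min", "max", "skew", "kurtosis")
N_TERMS = 13
N_STATS = 7
TARGET_LENGTH = N_TERMS * N_STATS + 1  # 92

_VARIANCE_FLOOR = 1e-12

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def interaction_energy(e_complex: float, e_protein: float,
                       e_ligand: float) -> float:
    """Interaction energy: complex minus isolated protein and ligand."""
    vals = (e_complex, e_protein, e_ligand)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite energy input {vals!r}")
    return e_complex - e_protein - e_ligand


def pk_from_constant(K: float) -> float:
    """pK = -log10(K / 1 M); K is a dissociation/inhibition constant."""
    if not (K > 0):
        raise ValueError(f"affinity constant must be positive, got {K!r}")
    return -math.log10(K)


def constant_from_pk(pk: float) -> float:
    """Inverse of :func:`pk_from_constant` (K in molar)."""
    return 10.0 ** (-pk)


def summarize_samples(values) -> np.ndarray:
    """The 7 summary statistics of one energy sample vector.

    Population moments (divisor n), skew = m3/m2^1.5, excess kurtosis
    = m4/m2^2 - 3; constant samples get std = skew = kurtosis = 0.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty sample vector")
    if not np.isfinite(x).all():
        raise ValueError("non-finite energy sample")
    m2 = float(np.var(x))  # population variance
    if m2 < _VARIANCE_FLOOR:
        std = skew = kurt = 0.0
    else:
        std = math.sqrt(m2)
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    return np.array(
        [float(np.mean(x)), float(np.median(x)), std,
         float(np.min(x)), float(np.max(x)), skew, kurt]
    )


@dataclass
class EnergySamples:
    """Per-iteration interaction energies for each of the 13 terms."""

    samples: dict[str, np.ndarray]
    term_names: tuple[str, ...] = DEFAULT_TERM_NAMES

    def __post_init__(self) -> None:
        self.term_names = tuple(self.term_names)
        if len(self.term_names) != N_TERMS:
            raise ValueError(f"expected {N_TERMS} terms, "
                             f"got {len(self.term_names)}")
        if len(set(self.term_names)) != N_TERMS:
            raise ValueError("term names must be unique")
        if REQUIRED_TERM not in self.term_names:
            raise ValueError(f"term set must include {REQUIRED_TERM}")
        lengths = set()
        for name in self.term_names:
            if name not in self.samples:
                raise ValueError(f"missing samples for term {name}")
            v = np.asarray(self.samples[name], dtype=np.float64)
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite samples in term {name}")
            self.samples[name] = v
            lengths.add(v.size)
        if len(lengths) != 1:
            raise ValueError(f"unequal sample counts across terms: {lengths}")
        self.n_iterations = lengths.pop()
        if self.n_iterations < 1:
            raise ValueError("at least one iteration required")

    def inactive_terms(self) -> list[str]:
        """Terms that are identically zero in this run."""
        return [t for t in self.term_names
                if np.all(self.samples[t] == 0.0)]


@dataclass
class SummaryTargets:
    """13x7 statistics matrix plus pK: the 92-long regression target."""

    stats: np.ndarray  # (13, 7) float64, terms-major in STAT_NAMES order
    pk: float
    term_names: tuple[str, ...] = DEFAULT_TERM_NAMES

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=np.float64)
        if self.stats.shape != (N_TERMS, N_STATS):
            raise ValueError(f"stats must be {N_TERMS}x{N_STATS}")

    def to_vector(self) -> np.ndarray:
        """Terms-major flattening with pK appended (length 92)."""
        return np.concatenate([self.stats.reshape(-1), [self.pk]])

    @classmethod
    def from_vector(cls, vec, term_names=DEFAULT_TERM_NAMES) -> "SummaryTargets":
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (TARGET_LENGTH,):
            raise ValueError(f"target vector must have length {TARGET_LENGTH}")
        return cls(vec[:-1].reshape(N_TERMS, N_STATS), float(vec[-1]),
                   term_names)

    def stat(self, term: str, stat: str) -> float:
        return float(self.stats[self.term_names.index(term),
                                STAT_NAMES.index(stat)])

    def validate(self) -> None:
        for row in self.stats:
            mean, median, std, lo, hi = row[0], row[1], row[2], row[3], row[4]
            if not (lo <= median <= hi and lo <= mean <= hi and std >= 0):
                raise ValueError("order-statistic invariants violated")


def summarize_energies(samples: EnergySamples, pk: float = np.nan
                       ) -> SummaryTargets:
    """Summary-statistics matrix of a docking run (pK attached as given)."""
    stats = np.stack([summarize_samples(samples.samples[t])
                      for t in samples.term_names])
    return SummaryTargets(stats, float(pk), samples.term_names)


def read_docking_table(csv_text: str,
                       term_names: tuple[str, ...] | None = None
                       ) -> EnergySamples:
    """Read a docking-run CSV (header = term names, one row per iteration)."""
    try:
        df = pd.read_csv(io.StringIO(csv_text))
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed docking table: {exc}") from exc
    if df.shape[0] < 1:
        raise ValueError("docking table has no iteration rows")
    if REQUIRED_TERM not in df.columns:
        raise ValueError(f"docking table lacks required column "
                         f"{REQUIRED_TERM}")
    names = tuple(term_names) if term_names is not None else tuple(df.columns)
    for col in names:
        if col not in df.columns:
            raise ValueError(f"docking table lacks column {col}")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(vals.isna())[0]
        if bad.size:
            raise ValueError(
                f"non-numeric value in column {col!r}, data row {bad[0] + 1}"
            )
        df[col] = vals
    return EnergySamples({c: df[c].to_numpy(dtype=np.float64) for c in names},
                         names)


def read_affinity_table(tsv_text: str) -> pd.DataFrame:
    """Read an affinity TSV (complex id, K value, unit, kind) and add pK.

    Kd and Ki are treated identically; units may be M/mM/uM/nM/pM.
    """
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t",
                     names=["complex_id", "K", "unit", "kind"], header=None,
                     comment="#")
    pks = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        if row.unit not in _UNIT_TO_MOLAR:
            raise ValueError(f"unknown unit {row.unit!r} in row {row_no}")
        if str(row.kind) not in ("Kd", "Ki"):
            raise ValueError(f"unknown constant kind {row.kind!r} "
                             f"in row {row_no}")
        pks.append(pk_from_constant(float(row.K) * _UNIT_TO_MOLAR[row.unit]))
    df["pk"] = pks
    return df
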