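"""Shared data containers for allele-specific bursting analysis.

The containers are deliberately thin: numpy arrays with identifier lists and
validation, plus small frozen parameter records. Anything tabular that leaves
the package goes through :mod:`allelicburst.io` as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214e23

__all__ = [
    "AVOGADRO",
    "KineticParams",
    "NoiseParams",
    "AllelicCountMatrix",
    "SpikeInSet",
]


@dataclass(frozen=True)
class KineticParams:
    """Two-state promoter kinetics, rates normalised by the mRNA decay rate.

    Parameters
    ----------
    k_on : float
        Activation rate (burst frequency), per mRNA lifetime.
    k_off : float
        Deactivation rate, per mRNA lifetime.
    s : float
        Transcription rate while the promoter is ON, per mRNA lifetime.

    Notes
    -----
    The decay rate ``d`` is fixed at 1 because only the stationary transcript
    distribution is observed; all three rates are therefore in units of the
    mRNA lifetime.  Burst size is ``s / k_off``: the mean number of transcripts
    synthesised per ON episode.
    """

    k_on: float
    k_off: float
    s: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be strictly positive")

    @property
    def burst_frequency(self) -> float:
        return self.k_on

    @property
    def burst_size(self) -> float:
        return self.s / self.k_off

    @property
    def mean_expression(self) -> float:
        """Stationary mean of the Poisson-Beta mixture, s*k_on/(k_on+k_off)."""
        return self.s * self.k_on / (self.k_on + self.k_off)


@dataclass(frozen=True)
class NoiseParams:
    """Batch-level technical-noise parameters of the dropout mixture model.

    Observed counts follow ``Q ~ Z * Poisson(alpha * Y**beta)`` with
    ``Z ~ Bernoulli(expit(kappa + tau * log Y))`` for true expression Y > 0.

    ``alpha`` absorbs capture and sequencing efficiency, ``beta`` models
    amplification bias, and (``kappa``, ``tau``) give the logistic
    detection-probability curve on log true expression.
    """

    alpha: float
    beta: float
    kappa: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (np.isfinite(self.kappa) and np.isfinite(self.tau)):
            raise ValueError("kappa and tau must be finite")

    @classmethod
    def identity(cls) -> "NoiseParams":
        """No amplification distortion and numerically-zero dropout.

        ``kappa=40`` puts the detection probability within 4e-18 of 1, so the
        repiling weights round to exactly 1.0 in double precision.
        """
        return cls(alpha=1.0, beta=1.0, kappa=40.0, tau=0.0)

    def detection_probability(self, y: np.ndarray) -> np.ndarray:
        """P(detected | true expression y), 0 where y == 0."""
        from scipy.special import expit

        y = np.asarray(y, dtype=float)
        out = np.zeros_like(y)
        pos = y > 0
        out[pos] = expit(self.kappa + self.tau * np.log(y[pos]))
        return out


def _check_ids(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicated {what} identifiers")
    return ids


@dataclass
class AllelicCountMatrix:
    """Observed allele-specific read counts, genes x cells, one locus per gene."""

    genes: list
    cells: list
    Q_A: np.ndarray
    Q_B: np.ndarray

    def __post_init__(self) -> None:
        self.genes = _check_ids(self.genes, "gene")
        self.cells = _check_ids(self.cells, "cell")
        self.Q_A = np.asarray(self.Q_A)
        self.Q_B = np.asarray(self.Q_B)
        if self.Q_A.shape != self.Q_B.shape:
            raise ValueError(
                f"allele matrices differ in shape: {self.Q_A.shape} vs {self.Q_B.shape}"
            )
        expected = (len(self.genes), len(self.cells))
        if self.Q_A.shape != expected:
            raise ValueError(
                f"count matrix shape {self.Q_A.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for name, m in (("Q_A", self.Q_A), ("Q_B", self.Q_B)):
            if np.any(m < 0):
                raise ValueError(f"{name} contains negative counts")
            if not np.allclose(m, np.round(m)):
                raise ValueError(f"{name} contains non-integer counts")
        self.Q_A = self.Q_A.astype(np.int64)
        self.Q_B = self.Q_B.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total(self) -> np.ndarray:
        """Q_A + Q_B, the non-allelic total coverage per gene per cell."""
        return self.Q_A + self.Q_B


@dataclass
class SpikeInSet:
    """Exogenous spike-in truth and observed reads across cells.

    ``concentration`` is in attomoles/uL before dilution; ``dilution_factor``
    is the fold-dilution applied to the spike-in mix (40,000 for the standard
    ERCC protocol); ``molecule_length`` is the spike-in length in bp and
    ``read_length`` the sequencing read length in bp (scalar for the batch).
    """

    spike_ids: list
    concentration: np.ndarray
    molecule_length: np.ndarray
    observed_reads: np.ndarray
    read_length: float = 100.0
    dilution_factor: float = 40000.0
    cells: list | None = None

    def __post_init__(self) -> None:
        self.spike_ids = _check_ids(self.spike_ids, "spike-in")
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.molecule_length = np.asarray(self.molecule_length, dtype=float)
        self.observed_reads = np.asarray(self.observed_reads)
        n = len(self.spike_ids)
        if self.concentration.shape != (n,) or self.molecule_length.shape != (n,):
            raise ValueError("concentration/length must have one entry per spike-in")
        if self.observed_reads.ndim != 2 or self.observed_reads.shape[0] != n:
            raise ValueError("observed_reads must be spike-ins x cells")
        if np.any(self.concentration < 0):
            raise ValueError("negative spike-in concentration")
        if np.any(self.molecule_length <= 0):
            raise ValueError("spike-in molecule lengths must be positive")
        if self.dilution_factor <= 0 or self.read_length <= 0:
            raise ValueError("dilution_factor and read_length must be positive")
        if np.any(self.observed_reads < 0):
            raise ValueError("negative spike-in read counts")
        if self.cells is not None:
            self.cells = _check_ids(self.cells, "cell")
            if len(self.cells) != self.observed_reads.shape[1]:
                raise ValueError("cell identifier count does not match read matrix")

    @property
    def n_cells(self) -> int:
        return self.observed_reads.shape[1]
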