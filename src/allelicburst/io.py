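"""TSV readers and writers for counts, spike-ins, size factors and results.

Formats: allele count matrices are tab-delimited with gene rows and cell
columns (first column = gene id); the spike-in table has columns
``spike_id``, ``concentration_attomol_per_ul``, ``length_bp`` followed by one
read-count column per cell; size factors are two-column (cell, value).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AllelicCountMatrix, SpikeInSet

__all__ = [
    "read_counts",
    "write_counts",
    "read_spike_ins",
    "write_spike_ins",
    "read_cell_sizes",
    "write_size_factors",
    "write_results",
    "write_dataset",
    "read_inputs",
]

_SPIKE_META = ["spike_id", "concentration_attomol_per_ul", "length_bp"]


def read_counts(path_a, path_b) -> AllelicCountMatrix:
    a = pd.read_csv(path_a, sep="\t", index_col=0)
    b = pd.read_csv(path_b, sep="\t", index_col=0)
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError(
            "allele-A and allele-B matrices must share identical gene rows "
            "and cell columns"
        )
    return AllelicCountMatrix(
        genes=list(a.index), cells=list(a.columns),
        Q_A=a.to_numpy(), Q_B=b.to_numpy(),
    )


def write_counts(counts: AllelicCountMatrix, path_a, path_b) -> None:
    for path, m in ((path_a, counts.Q_A), (path_b, counts.Q_B)):
        pd.DataFrame(m, index=counts.genes, columns=counts.cells).to_csv(
            path, sep="\t", index_label="gene"
        )


def read_spike_ins(path, read_length: float = 100.0,
                   dilution_factor: float = 40000.0) -> SpikeInSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SPIKE_META if c not in df.columns]
    if missing:
        raise ValueError(f"spike-in table is missing columns: {missing}")
    cell_cols = [c for c in df.columns if c not in _SPIKE_META]
    if not cell_cols:
        raise ValueError("spike-in table has no cell columns")
    return SpikeInSet(
        spike_ids=list(df["spike_id"]),
        concentration=df["concentration_attomol_per_ul"].to_numpy(),
        molecule_length=df["length_bp"].to_numpy(),
        observed_reads=df[cell_cols].to_numpy(),
        read_length=read_length,
        dilution_factor=dilution_factor,
        cells=cell_cols,
    )


def write_spike_ins(spikes: SpikeInSet, path) -> None:
    cells = spikes.cells or [f"cell{j}" for j in range(spikes.n_cells)]
    df = pd.DataFrame(
        {
            "spike_id": spikes.spike_ids,
            "concentration_attomol_per_ul": spikes.concentration,
            "length_bp": spikes.molecule_length,
        }
    )
    df = pd.concat(
        [df, pd.DataFrame(spikes.observed_reads, columns=cells)], axis=1
    )
    df.to_csv(path, sep="\t", index=False)


def read_cell_sizes(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 1].to_numpy(dtype=float)


def write_size_factors(cells, values, path, name: str = "value") -> None:
    pd.DataFrame({"cell": cells, name: values}).to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def write_dataset(sim, prefix) -> dict:
    """Write a simulated dataset in the same formats the CLI consumes.

    Emits allele-A/-B matrices, a cell-size table, and the ground-truth
    kinetics table; returns the path map.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "allele_a": f"{prefix}_alleleA.tsv",
        "allele_b": f"{prefix}_alleleB.tsv",
        "cell_sizes": f"{prefix}_cell_sizes.tsv",
        "truth": f"{prefix}_truth.tsv",
    }
    write_counts(sim.counts(), paths["allele_a"], paths["allele_b"])
    write_size_factors(sim.cells, sim.phi, paths["cell_sizes"], name="phi")
    rows = []
    for g, gene in enumerate(sim.genes):
        for allele, truth in (("A", sim.truth_A[g]), ("B", sim.truth_B[g])):
            rows.append(
                {"gene": gene, "allele": allele, "k_on": truth.k_on,
                 "k_off": truth.k_off, "s": truth.s}
            )
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_inputs(
    allele_a,
    allele_b,
    spikeins=None,
    cell_sizes=None,
    read_length: float = 100.0,
    dilution_factor: float = 40000.0,
):
    """Load and cross-validate all pipeline inputs.

    Returns ``(AllelicCountMatrix, SpikeInSet | None, phi | None)``.  When a
    spike-in table is given, its cells must match the count matrix cells.
    """
    counts = read_counts(allele_a, allele_b)
    spikes = None
    if spikeins is not None:
        spikes = read_spike_ins(spikeins, read_length, dilution_factor)
        if spikes.cells is not None and list(spikes.cells) != list(counts.cells):
            raise ValueError(
                "spike-in table cells do not match the count matrix cells"
            )
    phi = None
    if cell_sizes is not None:
        phi = read_cell_sizes(cell_sizes)
        if phi.size != counts.n_cells:
            raise ValueError("cell-size table length does not match cells")
    return counts, spikes, phi
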