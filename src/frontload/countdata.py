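"""Gene x sample count matrix with factorial design metadata.

The design is a 2 x 2 factorial: two genotypes contrasting in nitrogen-use
efficiency (high-NUE ``T29``, low-NUE ``T13``) under two nitrogen regimes
(control ``C``, nitrogen deficit ``T``), each cell with one or more
replicates.  :class:`CountMatrix` bundles the raw integer counts, the sample
sheet, and (optionally) gene lengths for FPKM computation.

On-disk formats are plain text: a counts TSV whose first column is the gene
id and whose remaining columns are samples named ``<genotype>_<condition>_r<k>``,
a sample sheet CSV with columns ``sample,genotype,condition,replicate``, and
an optional gene-length TSV with columns ``gene,length_bp``.  Lines starting
with ``#`` carry provenance (key=value) and are skipped on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

GENOTYPES = ("T29", "T13")
HIGH_NUE = "T29"
LOW_NUE = "T13"
CONDITIONS = ("C", "T")
CONTROL = "C"
N_DEFICIT = "T"

#: the four design cells in canonical order
CELLS = ("T29_C", "T29_T", "T13_C", "T13_T")


def other_genotype(genotype: str) -> str:
    if genotype not in GENOTYPES:
        raise DataError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    return GENOTYPES[1 - GENOTYPES.index(genotype)]


def parse_cell(label: str) -> tuple[str, str]:
    """Split a cell label like ``'T13_C'`` into (genotype, condition)."""
    parts = label.split("_")
    if len(parts) != 2 or parts[0] not in GENOTYPES or parts[1] not in CONDITIONS:
        raise DataError(
            f"bad group label {label!r}; expected <genotype>_<condition> "
            f"with genotype in {GENOTYPES} and condition in {CONDITIONS}"
        )
    return parts[0], parts[1]


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) plus sample design metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one integer column per sample.
    samples
        DataFrame indexed by sample id with columns ``genotype``,
        ``condition`` and ``replicate``; must cover exactly the columns of
        ``counts``.
    lengths
        Optional per-gene transcript length in bp (same index as counts).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise DataError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise DataError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise DataError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise DataError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        extra = set(self.samples.index) - set(self.counts.columns)
        if missing or extra:
            raise DataError(
                f"sample sheet does not match count columns "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for col in ("genotype", "condition"):
            if col not in self.samples.columns:
                raise DataError(f"sample sheet lacks required column {col!r}")
            bad = set(self.samples[col]) - set(
                GENOTYPES if col == "genotype" else CONDITIONS
            )
            if bad:
                raise DataError(f"unknown {col} values {sorted(bad)}")
        # align sample sheet to count column order
        self.samples = self.samples.loc[self.counts.columns]
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise DataError("gene lengths missing for some genes")
            if (self.lengths <= 0).any():
                raise DataError("gene lengths must be positive")

    # ------------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group(self, label: str) -> list[str]:
        """Sample ids belonging to a design cell, e.g. ``'T13_C'``."""
        genotype, condition = parse_cell(label)
        mask = (self.samples["genotype"] == genotype) & (
            self.samples["condition"] == condition
        )
        return list(self.samples.index[mask])

    def cells(self) -> dict[str, list[str]]:
        """Mapping of every design cell label to its sample ids."""
        return {cell: self.group(cell) for cell in CELLS}

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        samples_path: str | Path,
        lengths_path: str | Path | None = None,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
        samples = pd.read_csv(samples_path, comment="#", index_col=0)
        lengths = None
        if lengths_path is not None:
            lt = pd.read_csv(lengths_path, sep="\t", comment="#", index_col=0)
            lengths = lt.iloc[:, 0]
        return cls(counts=counts, samples=samples, lengths=lengths)

    def to_tsv(
        self,
        counts_path: str | Path,
        samples_path: str | Path,
        lengths_path: str | Path | None = None,
        header_meta: dict[str, object] | None = None,
    ) -> None:
        meta = "".join(f"# {k}={v}\n" for k, v in (header_meta or {}).items())
        with open(counts_path, "w") as fh:
            fh.write(meta)
            self.counts.rename_axis("gene").to_csv(fh, sep="\t")
        with open(samples_path, "w") as fh:
            fh.write(meta)
            self.samples.rename_axis("sample").to_csv(fh)
        if lengths_path is not None and self.lengths is not None:
            with open(lengths_path, "w") as fh:
                fh.write(meta)
                self.lengths.rename("length_bp").rename_axis("gene").to_csv(
                    fh, sep="\t"
                )
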