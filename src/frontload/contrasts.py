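"""The four canonical comparisons and set algebra over their DEG sets.

Orientation is fixed once and recorded in every output to avoid sign
confusion:

====  ==================  ==============================================
name  comparison          "up" means
====  ==================  ==============================================
R29   T29_T vs T29_C      higher under N deficit in the high-NUE genotype
R13   T13_T vs T13_C      higher under N deficit in the low-NUE genotype
GC    T29_C vs T13_C      higher in T29 under control
GT    T29_T vs T13_T      higher in T29 under N deficit
====  ==================  ==============================================

A gene is a *unique responder* of a genotype when it is a DEG in that
genotype's response contrast (R13 or R29) but not in the other's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from .countdata import CELLS, CountMatrix, other_genotype
from .de import ContrastSpec, estimate_size_factors, normalize, run_contrast
from .errors import DataError

#: canonical contrasts: name -> (denominator cell, numerator cell)
CONTRAST_SPECS: tuple[ContrastSpec, ...] = (
    ContrastSpec("R29", "T29_C", "T29_T"),
    ContrastSpec("R13", "T13_C", "T13_T"),
    ContrastSpec("GC", "T13_C", "T29_C"),
    ContrastSpec("GT", "T13_T", "T29_T"),
)

RESPONSE_CONTRAST = {"T29": "R29", "T13": "R13"}


@dataclass
class ContrastCatalog:
    """Results of the four canonical contrasts plus shared normalization."""

    results: dict[str, pd.DataFrame]
    size_factors: pd.Series
    cell_means: pd.DataFrame  # genes x the four cells, normalized means
    alpha_fdr: float

    def degs(self, name: str) -> set[str]:
        r = self._get(name)
        return set(r.index[r["is_deg"]])

    def up(self, name: str) -> set[str]:
        r = self._get(name)
        return set(r.index[r["direction"] == "up"])

    def down(self, name: str) -> set[str]:
        r = self._get(name)
        return set(r.index[r["direction"] == "down"])

    def _get(self, name: str) -> pd.DataFrame:
        if name not in self.results:
            raise DataError(f"unknown contrast {name!r}")
        return self.results[name]

    @property
    def genes(self) -> pd.Index:
        return self.cell_means.index

    def orientation(self) -> dict[str, str]:
        return {s.name: s.orientation for s in CONTRAST_SPECS}


def build_catalog(
    cm: CountMatrix,
    alpha_fdr: float = 0.05,
    pseudocount: float = 1.0,
    **contrast_kwargs,
) -> ContrastCatalog:
    """Run all four canonical contrasts with one shared set of size factors."""
    groups = cm.cells()
    missing = [cell for cell, ids in groups.items() if not ids]
    if missing:
        raise DataError(f"missing design cells: {missing}")
    sf = estimate_size_factors(cm)
    norm = normalize(cm, sf)
    cell_means = pd.DataFrame(
        {cell: norm[ids].mean(axis=1) for cell, ids in groups.items()},
        index=cm.genes,
    )[list(CELLS)]
    results = {
        spec.name: run_contrast(
            cm,
            spec.group_a,
            spec.group_b,
            alpha_fdr=alpha_fdr,
            size_factors=sf,
            pseudocount=pseudocount,
            **contrast_kwargs,
        )
        for spec in CONTRAST_SPECS
    }
    return ContrastCatalog(
        results=results, size_factors=sf, cell_means=cell_means, alpha_fdr=alpha_fdr
    )


@dataclass
class ResponderSets:
    """Gene sets derived from the catalog for one focal genotype."""

    focal_genotype: str
    unique: set[str] = field(default_factory=set)       # focal DEGs not in other
    unique_up: set[str] = field(default_factory=set)    # partitioned by focal direction
    unique_down: set[str] = field(default_factory=set)
    other_unique: set[str] = field(default_factory=set)
    common_response: set[str] = field(default_factory=set)  # R13 ∩ R29
    genotype_common: set[str] = field(default_factory=set)  # GC ∩ GT
    union_all: set[str] = field(default_factory=set)


def unique_responders(catalog: ContrastCatalog, focal_genotype: str) -> ResponderSets:
    """Genes significant in the focal genotype's response but not the other's."""
    focal_c = RESPONSE_CONTRAST[focal_genotype]
    other_c = RESPONSE_CONTRAST[other_genotype(focal_genotype)]
    focal_degs = catalog.degs(focal_c)
    other_degs = catalog.degs(other_c)
    unique = focal_degs - other_degs
    return ResponderSets(
        focal_genotype=focal_genotype,
        unique=unique,
        unique_up=catalog.up(focal_c) & unique,
        unique_down=catalog.down(focal_c) & unique,
        other_unique=other_degs - focal_degs,
        common_response=focal_degs & other_degs,
        genotype_common=catalog.degs("GC") & catalog.degs("GT"),
        union_all=focal_degs | other_degs | catalog.degs("GC") | catalog.degs("GT"),
    )


def venn_counts(catalog: ContrastCatalog) -> dict:
    """Pairwise DEG overlap counts plus the union over all four contrasts."""
    names = [s.name for s in CONTRAST_SPECS]
    sets = {n: catalog.degs(n) for n in names}
    pairs = {}
    for a, b in combinations(names, 2):
        pairs[f"{a}|{b}"] = {
            "a": len(sets[a]),
            "b": len(sets[b]),
            "overlap": len(sets[a] & sets[b]),
        }
    union = set().union(*sets.values())
    return {
        "per_contrast": {n: len(sets[n]) for n in names},
        "pairs": pairs,
        "union_all": len(union),
    }


def write_catalog(catalog: ContrastCatalog, outdir: str | Path) -> None:
    """Write per-contrast DE tables, gene-set lists and a summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    orient = catalog.orientation()
    for name, res in catalog.results.items():
        with open(outdir / f"de_{name}.tsv", "w") as fh:
            fh.write(f"# contrast={name}\n# orientation={orient[name]}\n")
            fh.write(f"# alpha_fdr={catalog.alpha_fdr}\n")
            res.rename_axis("gene").to_csv(fh, sep="\t")
        for direction, ids in (("up", catalog.up(name)), ("down", catalog.down(name))):
            with open(outdir / f"degs_{name}_{direction}.tsv", "w") as fh:
                fh.write(f"# contrast={name} direction={direction}\n")
                fh.write("gene\n")
                fh.writelines(f"{g}\n" for g in sorted(ids))
    summary = {
        "alpha_fdr": catalog.alpha_fdr,
        "orientation": orient,
        "deg_counts": {
            n: {"up": len(catalog.up(n)), "down": len(catalog.down(n))}
            for n in catalog.results
        },
        "venn": venn_counts(catalog),
    }
    (outdir / "catalog_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
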