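"""Replicate-correlation QC and qPCR (2^-ddCt) concordance checks.

Replicate QC follows the usual RNA-seq practice of correlating
log10(FPKM + 1) between biological replicates of the same library; pairs
below a configurable threshold (default r = 0.9) are flagged.

qPCR relative expression uses the 2^-ddCt method with a reference gene
(default 18S rRNA): dCt = mean Ct_target - mean Ct_reference within each of
the treatment and control cells, ddCt = dCt_treatment - dCt_control, and the
relative expression ratio is 2^-ddCt.  Technical replicates are aggregated
by the arithmetic mean of Ct before differencing; amplification efficiency
is fixed at 2 (no efficiency correction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

QPCR_COLUMNS = ("gene", "cell", "replicate", "ct_target", "ct_reference")
CELL_VALUES = ("treatment", "control")


# ----------------------------------------------------------------------
# replicate correlation
# ----------------------------------------------------------------------
def replicate_correlation(
    fpkm: pd.DataFrame,
    pairs: list[tuple[str, str]],
    warn_below: float = 0.9,
) -> pd.DataFrame:
    """Pearson r of log10(FPKM+1) across genes for each replicate pair."""
    if fpkm.shape[0] < 2:
        raise DataError("replicate correlation needs at least 2 genes")
    logf = np.log10(fpkm + 1.0)
    rows = []
    for a, b in pairs:
        if a not in logf.columns or b not in logf.columns:
            raise DataError(f"replicate pair ({a}, {b}) not found in FPKM matrix")
        r = float(np.corrcoef(logf[a], logf[b])[0, 1])
        rows.append({"replicate_1": a, "replicate_2": b, "r": r,
                     "flagged": bool(r < warn_below)})
    return pd.DataFrame(rows)


def replicate_pairs(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """All within-cell replicate pairs from a sample sheet."""
    pairs = []
    for _, grp in samples.groupby(["genotype", "condition"], sort=False):
        ids = list(grp.index)
        pairs.extend(
            (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
        )
    return pairs


# ----------------------------------------------------------------------
# 2^-ddCt
# ----------------------------------------------------------------------
def _check_qpcr(qpcr: pd.DataFrame) -> None:
    missing = set(QPCR_COLUMNS) - set(qpcr.columns)
    if missing:
        raise DataError(f"qPCR table lacks columns {sorted(missing)}")
    bad_cells = set(qpcr["cell"]) - set(CELL_VALUES)
    if bad_cells:
        raise DataError(f"qPCR cell must be one of {CELL_VALUES}, got {sorted(bad_cells)}")
    ct = qpcr[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise DataError("Ct values must be positive and finite")


def ddct(qpcr_gene: pd.DataFrame) -> float:
    """Relative expression ratio 2^-ddCt for one gene's qPCR records."""
    _check_qpcr(qpcr_gene)
    dct = {}
    for cell in CELL_VALUES:
        sub = qpcr_gene[qpcr_gene["cell"] == cell]
        if sub.empty:
            raise DataError(f"qPCR records missing the {cell} cell")
        dct[cell] = sub["ct_target"].mean() - sub["ct_reference"].mean()
    ddct_val = dct["treatment"] - dct["control"]
    return float(2.0 ** (-ddct_val))


def ddct_table(qpcr: pd.DataFrame) -> pd.Series:
    """2^-ddCt per gene from a long-format qPCR table."""
    _check_qpcr(qpcr)
    out = {gene: ddct(sub) for gene, sub in qpcr.groupby("gene", sort=False)}
    return pd.Series(out, name="ratio")


# ----------------------------------------------------------------------
# concordance with DE calls
# ----------------------------------------------------------------------
def concordance(
    qpcr_ratios: pd.Series,
    de_result: pd.DataFrame,
    deadband: float = 0.1,
) -> tuple[float, pd.DataFrame]:
    """Fraction of genes whose qPCR trend matches the DE direction.

    A gene is concordant when sign(log2 qPCR ratio) agrees with the DE
    direction; |log2 ratio| < ``deadband`` counts as no-change and matches
    direction 'none'.
    """
    common = qpcr_ratios.index.intersection(de_result.index)
    if len(common) == 0:
        raise DataError("no genes shared between qPCR table and DE result")
    log2r = np.log2(qpcr_ratios.loc[common].astype(float))
    qdir = pd.Series(
        np.where(log2r >= deadband, "up",
                 np.where(log2r <= -deadband, "down", "none")),
        index=common,
    )
    ddir = de_result.loc[common, "direction"]
    table = pd.DataFrame(
        {
            "qpcr_ratio": qpcr_ratios.loc[common],
            "qpcr_log2": log2r,
            "qpcr_trend": qdir,
            "de_direction": ddir,
            "concordant": (qdir == ddir),
        }
    )
    return float(table["concordant"].mean()), table


# ----------------------------------------------------------------------
# in-silico qPCR
# ----------------------------------------------------------------------
def simulate_qpcr(
    log2_fold_changes: pd.Series,
    rng: np.random.Generator,
    base_ct: float = 24.0,
    reference_ct: float = 15.0,
    noise_sd: float = 0.2,
    n_technical: int = 3,
) -> pd.DataFrame:
    """Simulate a long-format qPCR table realizing given log2 fold changes.

    Each doubling of expression lowers the target Ct by one cycle, so the
    treatment target Ct is base_ct - log2FC (plus N(0, noise_sd) technical
    noise per well); the reference gene is flat across cells.
    """
    rows = []
    for gene, lfc in log2_fold_changes.items():
        for cell, target in (("control", base_ct), ("treatment", base_ct - lfc)):
            for rep in range(1, n_technical + 1):
                rows.append(
                    {
                        "gene": gene,
                        "cell": cell,
                        "replicate": rep,
                        "ct_target": target + rng.normal(0, noise_sd),
                        "ct_reference": reference_ct + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows, columns=list(QPCR_COLUMNS))
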