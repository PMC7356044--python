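"""Ratio-plane classification of genotype-unique responsive genes.

Given the four normalized cell means of a gene, two cross-genotype ratios
locate it on the plane used to separate the responsive-pattern classes:

* ``r_C``: tolerant-genotype control mean over focal-genotype control mean
  (pseudocounted), and
* ``r_T``: the same ratio under nitrogen deficit,

where the *focal* genotype is the one carrying the unique response (default
the low-NUE one) and the tolerant genotype is the other.  ``rho_focal`` and
``rho_other`` are the within-genotype log control/treatment ratios
ln(mean_C/mean_T), used descriptively and by the direction-consistency
chi-square test.

Classification rules (strict inequalities at ratio 1, optional dead-band
``epsilon`` on the log scale):

* R0 *opposite*: significant in both response contrasts with discordant
  directions.
* For unique responders of the focal genotype with direction ``d``:

  - R1 *frontloaded*: d = up, r_C > 1 and r_T < 1 — the tolerant genotype
    is constitutively higher yet ends lower under stress (its response is
    muted because it had already frontloaded the expression).
  - R2 *relatively_upregulated*: d = down and r_T > 1 — the focal genotype
    drops while the tolerant genotype stays relatively higher under stress.
  - R3 *stress_tolerance*: (d = up and r_C <= 1) or (d = down, r_C <= 1 and
    r_T <= 1) — equal-or-lower constitutive level in the tolerant genotype
    and insensitivity to the stress.
  - R4: anything else is left unclassified.

Dual responders with concordant directions are unclassified (the shared
response carries no genotype-contrast information).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import RESPONSE_CONTRAST, ContrastCatalog
from .countdata import other_genotype
from .errors import DataError

LABELS = (
    "frontloaded",
    "stress_tolerance",
    "relatively_upregulated",
    "opposite",
    "unclassified",
)


def compute_ratios(
    cell_means: pd.DataFrame, focal_genotype: str = "T13", pseudocount: float = 1.0
) -> pd.DataFrame:
    """Cross-genotype and within-genotype expression ratios per gene.

    ``cell_means`` must have the four columns T29_C, T29_T, T13_C, T13_T
    (normalized means).  Returns columns r_C, r_T, rho_focal, rho_other.
    """
    other = other_genotype(focal_genotype)
    c = pseudocount
    fC = cell_means[f"{focal_genotype}_C"] + c
    fT = cell_means[f"{focal_genotype}_T"] + c
    oC = cell_means[f"{other}_C"] + c
    oT = cell_means[f"{other}_T"] + c
    out = pd.DataFrame(
        {
            "r_C": oC / fC,
            "r_T": oT / fT,
            "rho_focal": np.log(fC / fT),
            "rho_other": np.log(oC / oT),
        },
        index=cell_means.index,
    )
    out.attrs["focal_genotype"] = focal_genotype
    return out


def classify_gene(
    r_C: float,
    r_T: float,
    direction: str,
    in_focal: bool,
    in_other: bool,
    other_direction: str = "none",
    epsilon: float = 0.0,
) -> tuple[str, str]:
    """Label one responder gene; returns (label, rule id that fired)."""
    if not in_focal and not in_other:
        raise DataError("gene is not a responder in either genotype")
    if in_focal and in_other:
        if direction != other_direction and "none" not in (direction, other_direction):
            return "opposite", "R0"
        return "unclassified", "R4"
    if not in_focal:
        raise DataError(
            "gene responds only in the non-focal genotype; classify it under "
            "the mirrored focal instead"
        )
    # dead-band: |ln r| < epsilon counts as a tie (neither above nor below 1)
    above = lambda r: np.log(r) > epsilon
    below = lambda r: np.log(r) < -epsilon
    if direction == "up":
        if above(r_C) and below(r_T):
            return "frontloaded", "R1"
        if not above(r_C):
            return "stress_tolerance", "R3"
        return "unclassified", "R4"
    if direction == "down":
        if above(r_T):
            return "relatively_upregulated", "R2"
        if not above(r_C) and not above(r_T):
            return "stress_tolerance", "R3"
        return "unclassified", "R4"
    raise DataError(f"responder with undefined direction {direction!r}")


def classify_all(
    catalog: ContrastCatalog,
    focal_genotype: str = "T13",
    epsilon: float = 0.0,
    pseudocount: float = 1.0,
    ratios: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify every focal-unique and dual responder in the catalog.

    Returns a PatternTable: DataFrame indexed by gene with columns label,
    direction, r_C, r_T, rho_focal, rho_other, rule.  Labels partition the
    responder set (every responder gets exactly one label).
    """
    if ratios is None:
        ratios = compute_ratios(catalog.cell_means, focal_genotype, pseudocount)
    focal_res = catalog.results[RESPONSE_CONTRAST[focal_genotype]]
    other_res = catalog.results[RESPONSE_CONTRAST[other_genotype(focal_genotype)]]
    in_focal = focal_res["is_deg"]
    in_other = other_res["is_deg"]
    # unique responders of the focal genotype plus dual responders
    responders = catalog.genes[in_focal.to_numpy()]
    rows = []
    for g in responders:
        label, rule = classify_gene(
            ratios.at[g, "r_C"],
            ratios.at[g, "r_T"],
            focal_res.at[g, "direction"],
            bool(in_focal[g]),
            bool(in_other[g]),
            other_res.at[g, "direction"],
            epsilon=epsilon,
        )
        rows.append(
            {
                "gene": g,
                "label": label,
                "direction": focal_res.at[g, "direction"],
                "r_C": ratios.at[g, "r_C"],
                "r_T": ratios.at[g, "r_T"],
                "rho_focal": ratios.at[g, "rho_focal"],
                "rho_other": ratios.at[g, "rho_other"],
                "rule": rule,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "label", "direction", "r_C", "r_T",
            "rho_focal", "rho_other", "rule",
        ],
    ).set_index("gene")
    table.attrs["focal_genotype"] = focal_genotype
    table.attrs["epsilon"] = epsilon
    return table


def label_counts(table: pd.DataFrame) -> dict[str, int]:
    counts = {label: 0 for label in LABELS}
    counts.update(table["label"].value_counts().to_dict())
    return counts


def chi_square_direction(
    observed, null_probs=(0.5, 0.5)
) -> tuple[float, float]:
    """One-df goodness-of-fit of a two-cell split against given proportions.

    ``observed`` is the (n_greater_in_focal, n_greater_in_other) split of
    responder genes by which genotype shows the larger absolute expression
    change.  Default null is 50:50.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2,):
        raise DataError("observed must be a 2-cell count vector")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise DataError("observed counts must be non-negative integers")
    total = obs.sum()
    if total == 0:
        raise DataError("zero total count")
    expected = total * np.asarray(null_probs, dtype=float)
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def direction_consistency_test(table: pd.DataFrame) -> dict:
    """Chi-square test of where the larger response sits, over unique responders.

    Uses |rho_focal| vs |rho_other| of the genes in the pattern table whose
    rule is not R0 (i.e. the focal-unique responders); ties count toward the
    other genotype.
    """
    unique = table[table["rule"] != "R0"]
    if unique.empty:
        raise DataError("no unique responders to test")
    greater_focal = int(
        (unique["rho_focal"].abs() > unique["rho_other"].abs()).sum()
    )
    greater_other = len(unique) - greater_focal
    stat, p = chi_square_direction((greater_focal, greater_other))
    return {
        "n_greater_focal": greater_focal,
        "n_greater_other": greater_other,
        "statistic": stat,
        "p": p,
        "null": "50:50",
    }
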