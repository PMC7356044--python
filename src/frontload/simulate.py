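"""Synthetic factorial RNA-seq counts with planted expression archetypes.

The generator emulates the statistical structure of a two-genotype
(high-NUE tolerant vs low-NUE sensitive) by two-condition (control vs
nitrogen deficit) count experiment: per-gene baseline expression drawn
log-normally, negative-binomial sampling noise with a shared dispersion
``alpha`` (Var = mu + alpha * mu^2), multiplicative library-size variation,
and a planted "archetype" per gene that fixes the four cell means:

``frontloaded``
    Tolerant genotype constitutively higher (``constitutive_fold`` x baseline
    in both of its cells); the sensitive (focal) genotype responds up by
    ``response_fold`` under deficit.
``stress_tolerance_up`` / ``stress_tolerance_down``
    Tolerant genotype flat at a *lower* level; focal genotype responds up or
    down.  The tolerant level is baseline/constitutive_fold (up case) or
    baseline/(response_fold*constitutive_fold) (down case) so that the
    tolerant genotype sits below the focal one in both conditions.
``relatively_upregulated``
    Focal genotype responds down; tolerant genotype flat at baseline, hence
    relatively higher under deficit.
``opposite``
    Focal genotype up by ``response_fold``, tolerant genotype down by the
    same fold (a dual responder with discordant directions).
``constitutive``
    Tolerant genotype offset by ``constitutive_fold`` in both conditions; no
    treatment response in either genotype.
``null``
    One shared mean everywhere.

Every gene carries exactly one archetype; genes not covered by
``archetype_counts`` are null.  A truth table records the planted archetype
for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .countdata import GENOTYPES, CONDITIONS, CountMatrix, other_genotype
from .errors import ConfigError

ARCHETYPES = (
    "frontloaded",
    "stress_tolerance_up",
    "stress_tolerance_down",
    "relatively_upregulated",
    "opposite",
    "constitutive",
    "null",
)

#: default planted-class mix: 100 frontloaded, 20 stress-tolerance (10 up +
#: 10 down), 100 relatively upregulated, 4 opposite; the remaining genes of
#: the default 4,224-gene universe are null (4,000).
DEFAULT_ARCHETYPE_COUNTS: dict[str, int] = {
    "frontloaded": 100,
    "stress_tolerance_up": 10,
    "stress_tolerance_down": 10,
    "relatively_upregulated": 100,
    "opposite": 4,
    "constitutive": 0,
}


def scale_archetype_counts(
    n_genes: int, counts: Mapping[str, int] | None = None, reference: int = 4224
) -> dict[str, int]:
    """Scale an archetype mix proportionally to a different gene universe.

    Keeps at least one gene of every archetype present in the original mix,
    so small test universes still contain every planted class.
    """
    counts = DEFAULT_ARCHETYPE_COUNTS if counts is None else counts
    factor = n_genes / reference
    scaled = {
        k: (max(1, round(v * factor)) if v > 0 else 0) for k, v in counts.items()
    }
    if sum(scaled.values()) > n_genes:
        raise ConfigError(
            f"cannot fit archetype mix {counts} into {n_genes} genes"
        )
    return scaled


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic factorial count generator.

    Attributes
    ----------
    n_genes
        Total gene universe; genes beyond the planted archetypes are null.
    n_replicates
        Replicates per genotype x condition cell (default 3: the minimum
        giving the classification stage reasonable power; 2 mirrors typical
        pooled-sample designs and remains configurable).
    archetype_counts
        Planted genes per archetype; must sum to <= n_genes.
    baseline_log_mean, baseline_log_sd
        Natural-log mean and sd of the per-gene baseline expression level.
    dispersion
        Shared NB dispersion alpha in Var = mu + alpha*mu^2; 0 = Poisson.
    response_fold
        Treatment effect magnitude in the responding genotype (> 1).
    constitutive_fold
        Control-condition genotype offset for frontloaded/constitutive
        genes (> 1).
    library_size_factors
        One multiplicative factor per sample (length 4*n_replicates, sample
        order T29_C, T29_T, T13_C, T13_T with replicates innermost);
        ``None`` means all 1.
    focal_genotype
        The genotype carrying the unique response (default the low-NUE
        ``T13``; set ``T29`` for the mirrored analysis).
    seed
        RNG seed; the generator is deterministic given config + seed.
    """

    n_genes: int = 4224
    n_replicates: int = 3
    archetype_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_COUNTS)
    )
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    response_fold: float = 4.0
    constitutive_fold: float = 3.0
    library_size_factors: Sequence[float] | None = None
    focal_genotype: str = "T13"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ConfigError("n_replicates must be positive")
        unknown = set(self.archetype_counts) - set(ARCHETYPES)
        if unknown:
            raise ConfigError(f"unknown archetypes {sorted(unknown)}")
        if any(v < 0 for v in self.archetype_counts.values()):
            raise ConfigError("archetype counts must be non-negative")
        if sum(self.archetype_counts.values()) > self.n_genes:
            raise ConfigError(
                "archetype counts exceed n_genes "
                f"({sum(self.archetype_counts.values())} > {self.n_genes})"
            )
        if self.baseline_log_sd < 0:
            raise ConfigError("baseline_log_sd must be >= 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.response_fold <= 1 or self.constitutive_fold <= 1:
            raise ConfigError("response_fold and constitutive_fold must be > 1")
        if self.focal_genotype not in GENOTYPES:
            raise ConfigError(f"focal_genotype must be one of {GENOTYPES}")
        if self.library_size_factors is not None:
            lsf = np.asarray(self.library_size_factors, dtype=float)
            if lsf.shape != (4 * self.n_replicates,):
                raise ConfigError(
                    f"library_size_factors must have length {4 * self.n_replicates}"
                )
            if not (np.isfinite(lsf).all() and (lsf > 0).all()):
                raise ConfigError("library_size_factors must be finite and > 0")

    def sample_names(self) -> list[str]:
        return [
            f"{g}_{c}_r{k}"
            for g in GENOTYPES
            for c in CONDITIONS
            for k in range(1, self.n_replicates + 1)
        ]


def sample_nb_counts(
    mean: float, dispersion: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` NB counts with E[X]=mean and Var[X]=mean + dispersion*mean^2.

    ``dispersion == 0`` degenerates to Poisson.  Uses the (r, p)
    parameterization r = 1/dispersion, p = r/(r + mean).
    """
    if not np.isfinite(mean) or mean < 0:
        raise ConfigError(f"mean must be finite and >= 0, got {mean}")
    if dispersion < 0:
        raise ConfigError(f"dispersion must be >= 0, got {dispersion}")
    if mean == 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion == 0:
        return rng.poisson(mean, size=n).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n).astype(np.int64)


def _assign_archetypes(config: SimConfig) -> np.ndarray:
    labels = []
    for name in ARCHETYPES[:-1]:
        labels.extend([name] * config.archetype_counts.get(name, 0))
    labels.extend(["null"] * (config.n_genes - len(labels)))
    return np.asarray(labels, dtype=object)


def cell_mean_table(config: SimConfig, baseline: np.ndarray, archetype: np.ndarray) -> pd.DataFrame:
    """Expected (pre-library-scaling) count per design cell for each gene."""
    focal = config.focal_genotype
    other = other_genotype(focal)
    f = config.response_fold
    g = config.constitutive_fold
    b = baseline
    means = {
        f"{focal}_C": np.array(b, dtype=float),
        f"{focal}_T": np.array(b, dtype=float),
        f"{other}_C": np.array(b, dtype=float),
        f"{other}_T": np.array(b, dtype=float),
    }

    def setrule(name: str, fC: float, fT: float, oC: float, oT: float) -> None:
        m = archetype == name
        means[f"{focal}_C"][m] = b[m] * fC
        means[f"{focal}_T"][m] = b[m] * fT
        means[f"{other}_C"][m] = b[m] * oC
        means[f"{other}_T"][m] = b[m] * oT

    setrule("frontloaded", 1, f, g, g)
    setrule("stress_tolerance_up", 1, f, 1 / g, 1 / g)
    setrule("stress_tolerance_down", 1, 1 / f, 1 / (f * g), 1 / (f * g))
    setrule("relatively_upregulated", 1, 1 / f, 1, 1)
    setrule("opposite", 1, f, 1, 1 / f)
    setrule("constitutive", 1, 1, g, g)
    # null: baseline everywhere (already set)
    return pd.DataFrame(means)


def generate_dataset(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a factorial count matrix and its planted truth table.

    Returns
    -------
    (CountMatrix, truth)
        ``truth`` is a DataFrame indexed by gene with a single ``archetype``
        column; ``truth.attrs['focal_genotype']`` records the responder.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index(
        [f"g{i:06d}" for i in range(1, config.n_genes + 1)], name="gene"
    )
    archetype = _assign_archetypes(config)
    if config.baseline_log_sd > 0:
        baseline = np.exp(
            rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
        )
    else:
        baseline = np.full(config.n_genes, np.exp(config.baseline_log_mean))

    cell_means = cell_mean_table(config, baseline, archetype)

    sample_names = config.sample_names()
    lsf = (
        np.ones(len(sample_names))
        if config.library_size_factors is None
        else np.asarray(config.library_size_factors, dtype=float)
    )
    # per-sample expected counts: cell mean scaled by the library factor
    mu = np.empty((config.n_genes, len(sample_names)))
    for j, name in enumerate(sample_names):
        cell = name.rsplit("_r", 1)[0]
        mu[:, j] = cell_means[cell].to_numpy() * lsf[j]

    if config.dispersion == 0:
        counts = rng.poisson(mu).astype(np.int64)
    else:
        r = 1.0 / config.dispersion
        p = np.where(mu > 0, r / (r + mu), 1.0)
        counts = rng.negative_binomial(r, p).astype(np.int64)

    lengths = pd.Series(
        np.exp(rng.uniform(np.log(200.0), np.log(10_000.0), config.n_genes)).round(),
        index=genes,
        name="length_bp",
    )

    samples = pd.DataFrame(
        {
            "genotype": [s.split("_")[0] for s in sample_names],
            "condition": [s.split("_")[1] for s in sample_names],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in sample_names],
        },
        index=pd.Index(sample_names, name="sample"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_names),
        samples=samples,
        lengths=lengths,
    )
    truth = pd.DataFrame({"archetype": archetype}, index=genes)
    truth.attrs["focal_genotype"] = config.focal_genotype
    return cm, truth


def write_dataset(
    cm: CountMatrix,
    truth: pd.DataFrame,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> None:
    """Write counts/sample-sheet/truth/lengths as TSV/CSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: dict[str, object] = {}
    if config is not None:
        meta = {"seed": config.seed, "n_genes": config.n_genes,
                "focal_genotype": config.focal_genotype}
    cm.to_tsv(
        outdir / "counts.tsv",
        outdir / "samples.csv",
        outdir / "gene_lengths.tsv",
        header_meta=meta,
    )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("".join(f"# {k}={v}\n" for k, v in meta.items()))
        truth.rename_axis("gene").to_csv(fh, sep="\t")
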