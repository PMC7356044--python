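"""End-to-end pipeline: simulate (or load) -> DE -> contrasts -> classify -> QC.

A single :class:`PipelineConfig` drives every stage; all randomness flows
from its one seed, every artifact is written under a deterministic name, and
the machine-readable run summary contains every number needed to reproduce a
report of the analysis (per-contrast DEG counts, unique-responder counts,
pattern-class counts, the direction chi-square, qPCR concordance, and —
when a truth table is available — per-class recovery metrics).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import contrasts as _contrasts
from . import de as _de
from . import qc as _qc
from .countdata import CountMatrix
from .errors import ConfigError, DataError, InvariantError
from .simulate import SimConfig, generate_dataset, write_dataset

log = logging.getLogger(__name__)

RECOVERY_CLASS_MAP = {
    "frontloaded": "frontloaded",
    "stress_tolerance_up": "stress_tolerance",
    "stress_tolerance_down": "stress_tolerance",
    "relatively_upregulated": "relatively_upregulated",
    "opposite": "opposite",
}


@dataclass
class PipelineConfig:
    """Everything needed for one full run.

    Either ``counts_path``/``samples_path`` point at an existing dataset, or
    ``sim`` parameters are used to generate one (the default).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    counts_path: str | None = None
    samples_path: str | None = None
    lengths_path: str | None = None
    truth_path: str | None = None
    alpha_fdr: float = 0.05
    epsilon: float = 0.0
    pseudocount: float = 1.0
    qpcr: bool = True
    n_qpcr_genes: int = 15
    qpcr_ct_sd: float = 0.2
    replicate_r_warn: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fdr < 1:
            raise ConfigError("alpha_fdr must lie in (0, 1)")
        if self.epsilon < 0 or self.pseudocount < 0:
            raise ConfigError("epsilon and pseudocount must be >= 0")
        if (self.counts_path is None) != (self.samples_path is None):
            raise ConfigError("counts_path and samples_path must be given together")

    @property
    def focal_genotype(self) -> str:
        return self.sim.focal_genotype

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if d["sim"]["library_size_factors"] is not None:
            d["sim"]["library_size_factors"] = list(
                map(float, d["sim"]["library_size_factors"])
            )
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        try:
            return cls(sim=sim, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def score_recovery(labels: pd.Series, truth: pd.Series) -> dict[str, dict[str, float]]:
    """Per-class precision/recall of predicted labels against planted archetypes.

    ``labels`` may cover only the responder genes; genes planted with an
    archetype but absent from ``labels`` count as misses.  Archetypes map
    onto predicted classes via up/down stress-tolerance merging.
    """
    if len(labels.index.intersection(truth.index)) == 0 and len(truth) > 0:
        raise DataError("pattern table and truth table share no genes")
    mapped_truth = truth.map(RECOVERY_CLASS_MAP)  # NaN for constitutive/null
    full_labels = labels.reindex(truth.index).fillna("unclassified")
    out: dict[str, dict[str, float]] = {}
    for cls in ("frontloaded", "stress_tolerance", "relatively_upregulated", "opposite"):
        truth_pos = mapped_truth == cls
        pred_pos = full_labels == cls
        tp = int((truth_pos & pred_pos).sum())
        fp = int((~truth_pos & pred_pos).sum())
        fn = int((truth_pos & ~pred_pos).sum())
        out[cls] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
        }
    return out


def _load_or_simulate(
    config: PipelineConfig, outdir: Path
) -> tuple[CountMatrix, pd.DataFrame | None]:
    if config.counts_path is not None:
        cm = CountMatrix.from_tsv(
            config.counts_path, config.samples_path, config.lengths_path
        )
        truth = None
        if config.truth_path is not None:
            truth = pd.read_csv(
                config.truth_path, sep="\t", comment="#", index_col=0
            )
        log.info("loaded %d genes x %d samples", cm.n_genes, cm.n_samples)
        return cm, truth
    cm, truth = generate_dataset(config.sim)
    write_dataset(cm, truth, outdir / "data", config.sim)
    log.info(
        "simulated %d genes x %d samples (seed %d)",
        cm.n_genes, cm.n_samples, config.sim.seed,
    )
    return cm, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages and write artifacts; returns the run summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "warnings": [],
    }

    cm, truth = _load_or_simulate(config, outdir)
    focal = config.focal_genotype

    # --- contrasts -----------------------------------------------------
    catalog = _contrasts.build_catalog(
        cm, alpha_fdr=config.alpha_fdr, pseudocount=config.pseudocount
    )
    _contrasts.write_catalog(catalog, outdir / "contrasts")
    responders = _contrasts.unique_responders(catalog, focal)
    summary["deg_counts"] = {
        name: {"up": len(catalog.up(name)), "down": len(catalog.down(name))}
        for name in catalog.results
    }
    summary["orientation"] = catalog.orientation()
    summary["venn"] = _contrasts.venn_counts(catalog)
    summary["unique_responders"] = {
        focal: len(responders.unique),
        f"{focal}_up": len(responders.unique_up),
        f"{focal}_down": len(responders.unique_down),
        "other": len(responders.other_unique),
        "common_response": len(responders.common_response),
        "genotype_common": len(responders.genotype_common),
        "union_all": len(responders.union_all),
    }

    # --- classification ------------------------------------------------
    table = _classify.classify_all(
        catalog, focal, epsilon=config.epsilon, pseudocount=config.pseudocount
    )
    counts = _classify.label_counts(table)
    n_responders = int(
        catalog.results[_contrasts.RESPONSE_CONTRAST[focal]]["is_deg"].sum()
    )
    if sum(counts.values()) != len(table) or len(table) != n_responders:
        raise InvariantError("pattern labels do not partition the responder set")
    summary["pattern_counts"] = counts
    with open(outdir / "pattern_table.tsv", "w") as fh:
        fh.write(f"# focal_genotype={focal}\n# epsilon={config.epsilon}\n")
        table.rename_axis("gene").to_csv(fh, sep="\t")
    try:
        summary["chi_square_direction"] = _classify.direction_consistency_test(table)
    except DataError as exc:
        summary["chi_square_direction"] = None
        summary["warnings"].append(f"chi-square skipped: {exc}")

    # --- QC -------------------------------------------------------------
    if cm.lengths is not None:
        fpkm = _de.compute_fpkm(cm)
        rep_corr = _qc.replicate_correlation(
            fpkm, _qc.replicate_pairs(cm.samples), warn_below=config.replicate_r_warn
        )
        rep_corr.to_csv(outdir / "replicate_correlation.tsv", sep="\t", index=False)
        summary["replicate_correlation"] = {
            "min_r": float(rep_corr["r"].min()),
            "n_flagged": int(rep_corr["flagged"].sum()),
        }
    else:
        summary["replicate_correlation"] = None
        summary["warnings"].append("no gene lengths: replicate QC skipped")

    if config.qpcr:
        focal_res = catalog.results[_contrasts.RESPONSE_CONTRAST[focal]]
        degs = focal_res[focal_res["is_deg"]].sort_values("padj")
        picked = degs.head(config.n_qpcr_genes)
        if picked.empty:
            summary["qpcr_concordance"] = None
            summary["warnings"].append("no DEGs available for qPCR validation")
        else:
            # in-silico positive control: plant the observed fold changes
            qrng = np.random.default_rng(config.sim.seed + 1_000_003)
            qpcr = _qc.simulate_qpcr(
                picked["log2fc"], qrng, noise_sd=config.qpcr_ct_sd
            )
            qpcr.to_csv(outdir / "qpcr.csv", index=False)
            ratios = _qc.ddct_table(qpcr)
            frac, conc_table = _qc.concordance(ratios, focal_res)
            conc_table.rename_axis("gene").to_csv(
                outdir / "qpcr_concordance.tsv", sep="\t"
            )
            summary["qpcr_concordance"] = {
                "fraction": frac,
                "n_genes": int(len(conc_table)),
            }

    # --- recovery -------------------------------------------------------
    if truth is not None:
        summary["recovery"] = score_recovery(table["label"], truth["archetype"])
    else:
        summary["recovery"] = None

    (outdir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    return summary


def format_report(summary: dict[str, Any]) -> str:
    """Human-readable digest of a run summary."""
    lines = [f"config hash: {summary['config_hash']} (seed {summary['seed']})"]
    lines.append("DEG counts (up/down):")
    for name, c in summary["deg_counts"].items():
        lines.append(
            f"  {name:>3} [{summary['orientation'][name]}]: "
            f"{c['up']} up, {c['down']} down"
        )
    ur = summary["unique_responders"]
    focal = summary["config"]["sim"]["focal_genotype"]
    lines.append(
        f"unique responders in {focal}: {ur[focal]} "
        f"({ur[focal + '_up']} up, {ur[focal + '_down']} down); "
        f"common response: {ur['common_response']}; union of all DEGs: {ur['union_all']}"
    )
    lines.append("pattern classes: " + ", ".join(
        f"{k}={v}" for k, v in summary["pattern_counts"].items()
    ))
    chi = summary.get("chi_square_direction")
    if chi:
        lines.append(
            f"direction chi-square ({chi['n_greater_focal']} vs "
            f"{chi['n_greater_other']}, null {chi['null']}): "
            f"stat={chi['statistic']:.3f}, p={chi['p']:.3g}"
        )
    if summary.get("qpcr_concordance"):
        q = summary["qpcr_concordance"]
        lines.append(
            f"qPCR concordance: {q['fraction']:.2%} of {q['n_genes']} genes"
        )
    if summary.get("recovery"):
        lines.append("recovery vs planted truth (precision/recall):")
        for cls, m in summary["recovery"].items():
            lines.append(
                f"  {cls}: {m['precision']:.3f}/{m['recall']:.3f} "
                f"(tp={m['tp']} fp={m['fp']} fn={m['fn']})"
            )
    for w in summary.get("warnings", []):
        lines.append(f"warning: {w}")
    return "\n".join(lines)
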