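"""End-to-end pipeline: counts + traits in, module-trait report out.

Stages: (optional) simulate -> preprocess (filters + median-of-ratios
normalization) -> differential expression -> co-expression modules ->
module-trait association with jack-knife screening -> term enrichment.
Every stage writes TSV artifacts into the output directory and the run
manifest records seeds, thresholds, checksums and per-stage gene/sample
counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import diffexp, enrichment, preprocess, simulate
from .network import CoexpressionModules
from .trait_assoc import ModuleTraitAssociation, association_summary

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """One structured configuration for a full run.

    Either ``counts``/``samples``/``traits`` paths are given, or
    ``simulate = True`` generates a synthetic dataset first. Every analysis
    threshold of the emulated study appears as a named key with that study's
    value as its default.
    """

    outdir: str = "coexphys_run"
    counts: str | None = None
    samples: str | None = None
    traits: str | None = None
    annotations: str | None = None          # GMT or term/gene TSV
    term_pathways: str | None = None        # term -> pathway TSV
    simulate: bool = False
    simulate_overrides: dict = dataclasses.field(default_factory=dict)
    # preprocess
    min_count: int = 30
    min_fraction: float = 0.10
    min_total_reads: float = 0.0
    # differential expression
    de_alpha: float = 0.05
    run_de: bool = True
    # network
    power: float = 6.0
    network_type: str = "unsigned"
    min_module_size: int = 30
    merge_threshold: float = 0.75
    # association
    jackknife_frac: float = 0.9
    jackknife_reps: int = 100
    jackknife_alpha: float = 0.05
    min_support: int = 70
    assoc_fdr: float = 0.05
    # enrichment
    enrich_fdr: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _read_tsv(path, what: str) -> pd.DataFrame:
    path = Path(path) if path else None
    if path is None or not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # ------------------------------------------------------------------ input
    if config.simulate:
        sim_cfg = simulate.SimulationConfig(
            seed=config.seed, **config.simulate_overrides)
        dataset = simulate.simulate_dataset(sim_cfg)
        dataset.write(out / "synthetic")
        counts, samples, traits = dataset.counts, dataset.samples, dataset.traits
        manifest["stages"]["simulate"] = {
            "checksum": dataset.checksum(),
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
        }
    else:
        counts = _read_tsv(config.counts, "counts")
        samples = _read_tsv(config.samples, "samples")
        traits = _read_tsv(config.traits, "traits")
        for name, p in (("counts", config.counts), ("samples", config.samples),
                        ("traits", config.traits)):
            manifest.setdefault("inputs", {})[name] = _sha(Path(p))

    # ------------------------------------------------------------- preprocess
    kept_samples = preprocess.filter_samples(counts, config.min_total_reads)
    counts = counts[kept_samples]
    samples = samples.loc[kept_samples]
    traits = traits.loc[kept_samples]
    kept_genes = preprocess.filter_genes(counts, config.min_count,
                                         config.min_fraction)
    counts = counts.loc[kept_genes]
    norm = preprocess.normalize(counts)
    norm.size_factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
    norm.log_values.to_csv(out / "log_normalized.tsv", sep="\t",
                           index_label="gene_id")
    manifest["stages"]["preprocess"] = {
        "n_genes_kept": int(counts.shape[0]),
        "n_samples_kept": int(counts.shape[1]),
        "min_count": config.min_count,
        "min_fraction": config.min_fraction,
    }
    logger.info("preprocess: kept %d genes x %d samples", *counts.shape)

    # --------------------------------------------------- differential expression
    if config.run_de and samples["acclimation"].nunique() == 2:
        de = diffexp.NegativeBinomialDE(alpha=config.de_alpha).fit(
            counts, samples, norm.size_factors)
        de.results_.to_csv(out / "de_acclimation.tsv", sep="\t", index=False)
        deg_sets = {pop: de.significant_genes(f"{pop}_28v12")
                    for pop in simulate.POPULATIONS}
        venn = diffexp.overlap_counts(deg_sets)
        (out / "de_venn.json").write_text(json.dumps(venn, indent=2))
        manifest["stages"]["diffexp"] = {
            "n_deg_per_population": {k: len(v) for k, v in deg_sets.items()},
            "shared_fraction": venn["shared_fraction"],
        }

    # ---------------------------------------------------------------- network
    detector = CoexpressionModules(
        power=config.power, network_type=config.network_type,
        min_module_size=config.min_module_size,
        merge_threshold=config.merge_threshold)
    detector.fit(norm.log_values.T)
    detector.gene_labels_.to_frame().to_csv(out / "module_labels.tsv", sep="\t")
    detector.eigengenes_.to_csv(out / "eigengenes.tsv", sep="\t",
                                index_label="sample_id")
    detector.module_summary_.to_csv(out / "module_summary.tsv", sep="\t",
                                    index=False)
    manifest["stages"]["network"] = {
        "n_modules": int(detector.eigengenes_.shape[1]),
        "power": config.power,
        "n_unassigned": int((detector.labels_ == 0).sum()),
    }
    logger.info("network: %d modules", detector.eigengenes_.shape[1])

    # ------------------------------------------------------------ association
    assoc_frames = []
    multiple_r: dict[str, dict[str, float]] = {}
    for temp, group in samples.groupby("acclimation"):
        idx = group.index
        if len(idx) < 10 or detector.eigengenes_.empty:
            continue
        assoc = ModuleTraitAssociation(
            frac=config.jackknife_frac, reps=config.jackknife_reps,
            alpha=config.jackknife_alpha, min_support=config.min_support,
            fdr=config.assoc_fdr, seed=config.seed)
        assoc.fit(detector.eigengenes_.loc[idx], traits.loc[idx],
                  samples.loc[idx])
        res = assoc.results_.copy()
        res.insert(0, "acclimation", temp)
        assoc_frames.append(res)
        multiple_r[str(temp)] = assoc.multiple_correlations_
    if assoc_frames:
        assoc_all = pd.concat(assoc_frames, ignore_index=True)
        assoc_all.to_csv(out / "associations.tsv", sep="\t", index=False)
        summary = association_summary(assoc_all[assoc_all["pass"]])
        summary.to_csv(out / "association_summary.tsv", sep="\t", index=False)
        (out / "multiple_correlations.json").write_text(
            json.dumps(multiple_r, indent=2))
        manifest["stages"]["trait_assoc"] = {
            "n_pass": int(assoc_all["pass"].sum()),
            "n_tested": int(len(assoc_all)),
        }

    # ------------------------------------------------------------- enrichment
    if config.annotations:
        ann = enrichment.load_gene_sets(config.annotations)
        if config.term_pathways:
            enrichment.load_term_pathways(config.term_pathways, ann)
        universe = set(counts.index)
        enr = enrichment.enrich_all_modules(
            detector.gene_labels_, ann, universe, config.enrich_fdr)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        pathways = []
        for m in sorted(set(detector.gene_labels_) - {0}):
            sub = enr[enr["module"] == m]
            pw, count, tie = enrichment.top_pathway(sub, ann)
            pathways.append((m, pw, count, tie))
        pd.DataFrame(pathways,
                     columns=["module", "top_pathway", "n_terms", "tie"]
                     ).to_csv(out / "top_pathways.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {
            "n_significant_terms": int(enr["significant"].sum())
            if len(enr) else 0,
        }

    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out


def render_report(outdir) -> str:
    """Deterministic plain-text summary of a pipeline output directory."""
    out = Path(outdir)
    lines = ["# coexphys run report", ""]
    manifest = out / "manifest.json"
    if manifest.exists():
        m = json.loads(manifest.read_text())
        lines.append(f"seed: {m.get('seed')}")
        for stage, info in m.get("stages", {}).items():
            lines.append(f"stage {stage}: "
                         + ", ".join(f"{k}={v}" for k, v in info.items()))
        lines.append("")
    mod = out / "module_summary.tsv"
    if mod.exists():
        lines.append("## Modules (size, hub, hub MM, positive-MM fraction)")
        lines.append(mod.read_text().rstrip())
        lines.append("")
    else:
        lines.append("warning: no module summary found")
    assoc = out / "association_summary.tsv"
    if assoc.exists():
        df = pd.read_csv(assoc, sep="\t")
        lines.append("## Passing module-trait associations")
        if df.empty:
            lines.append("(no associations passed FDR + jack-knife; "
                         "AVERAGE row omitted)")
        else:
            lines.append(df.to_string(index=False))
        lines.append("")
    venn = out / "de_venn.json"
    if venn.exists():
        lines.append("## Acclimation DEG overlap among populations")
        lines.append(venn.read_text().rstrip())
        lines.append("")
    return "\n".join(lines)
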