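"""End-to-end pipeline: simulate/load -> filter -> series -> LSA ->
networks -> comparison -> community statistics, with a checksum manifest.

Every stage writes its outputs as TSV (networks also as GraphML) under the
output directory, and ``run_pipeline`` records a manifest with the config
hash, seed, and a sha256 per output so identical config + seed gives
byte-identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import community, network, tables
from .lsa import LsaConfig, LsaResult, all_pairs_lsa, results_to_frame
from .simulate import GroundTruth, SimConfig, simulate_dataset, write_dataset
from .tables import AbundanceTable, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.001, 0.005, 0.01, 0.05, 0.1)


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``table_path`` (with ``metadata_path``) or ``sim`` must
    be given.  Thresholds default to the standard settings of this kind of
    study: 1 % maximum-abundance node filter, 7.5 % heatmap filter,
    rarefaction to the observed minimum depth, delay-1 LSA.
    """

    out_dir: str | Path = "elsanet_run"
    table_path: str | Path | None = None
    metadata_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    sim: SimConfig | None = None
    lsa: LsaConfig = field(default_factory=LsaConfig)
    alpha: float = 0.05
    alphas: Sequence[float] = DEFAULT_ALPHAS
    node_filter: float = 0.01
    heatmap_threshold: float = 0.075
    rarefaction_depth: int | None = None  # None -> observed minimum
    top_k_families: int = 7
    permanova_permutations: int = 999
    bh_correction: bool = False  # optional Benjamini-Hochberg on LSA p-values
    seed: int = 1

    def __post_init__(self) -> None:
        if (self.table_path is None) == (self.sim is None):
            raise ValidationError("exactly one of table_path or sim must be provided")
        if self.table_path is not None and self.metadata_path is None:
            raise ValidationError("metadata_path is required with table_path")
        for thr in (self.node_filter, self.heatmap_threshold):
            if not 0 < thr < 1:
                raise ValidationError(f"thresholds must be in (0, 1), got {thr}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, (Path, np.integer, np.floating)):
            return str(o)
        return repr(o)

    payload = asdict(config)
    payload.pop("out_dir", None)  # the analytic config, not the output location
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        truth: GroundTruth | None = None
        taxonomy: dict[str, str] | None = None
        if config.sim is not None:
            stage = "simulate"
            sim = config.sim
            counts, truth = simulate_dataset(sim)
            write_dataset(counts, truth, out)
            taxonomy = truth.taxonomy
            logger.info("simulate: %d samples x %d OTUs", *counts.shape)
        else:
            stage = "read"
            counts = tables.read_abundance(config.table_path, config.metadata_path)
            if config.taxonomy_path:
                taxonomy = tables.read_taxonomy(config.taxonomy_path)
            logger.info("read: %d samples x %d OTUs", *counts.shape)

        stage = "rarefy"
        depth = config.rarefaction_depth or int(counts.data.sum(axis=1).min())
        rarefied = community.rarefy(counts, depth, seed=config.seed)
        tables.write_abundance(rarefied, out / "rarefied_table.tsv", out / "metadata.tsv")
        logger.info("rarefy: depth %d", depth)

        stage = "relative"
        rel = tables.to_relative(rarefied)
        stage = "node_filter"
        filtered = tables.filter_prevalent_otus(rel, config.node_filter)
        filtered.data.to_csv(out / "filtered_relative.tsv", sep="\t", index_label="sample_id")
        logger.info("node_filter: %d of %d OTUs retained at %.3g",
                    filtered.shape[1], rel.shape[1], config.node_filter)

        stage = "lsa"
        treatments = sorted(rel.metadata["treatment"].unique())
        results: dict[str, list[LsaResult]] = {}
        for t in treatments:
            series = tables.build_series(filtered, t)
            res = all_pairs_lsa(series, config.lsa)
            if config.bh_correction:
                res = benjamini_hochberg(res)
            results[t] = res
            results_to_frame(res).to_csv(out / f"lsa_{t}.tsv", sep="\t", index=False)
            logger.info("lsa[%s]: %d pairs", t, len(res))

        stage = "networks"
        nodes = filtered.otu_ids
        nets = {
            t: network.build_network(results[t], nodes, config.alpha, t, taxonomy)
            for t in treatments
        }
        for t, g in nets.items():
            network.write_graphml(g, out / f"network_{t}.graphml")
            network.write_edge_list(g, out / f"edges_{t}.tsv")
            logger.info("network[%s]: %d edges on %d nodes", t,
                        g.number_of_edges(), g.number_of_nodes())

        stage = "modules"
        module_rows = []
        for t, g in nets.items():
            if g.number_of_edges() == 0:
                logger.warning("network[%s] is edgeless; modules skipped", t)
                continue
            part = network.detect_modules(g, seed=config.seed)
            for top in network.largest_modules(part, g, k=min(2, len(part.module_sizes))):
                module_rows.append(
                    {"treatment": t, "module_id": top["module_id"], "size": top["size"],
                     "within_edges": top["within_edges"], "modularity": part.modularity,
                     "taxa": json.dumps(top["taxa"], sort_keys=True)}
                )
        pd.DataFrame(module_rows).to_csv(out / "modules.tsv", sep="\t", index=False)

        stage = "comparison"
        network.compare_networks(nets).to_csv(out / "network_comparison.tsv", sep="\t",
                                              index_label="treatment")
        network.alpha_scan(results, nodes, list(config.alphas)).to_csv(
            out / "alpha_scan.tsv", sep="\t", index=False
        )

        stage = "diversity"
        div = community.shannon_per_sample(rarefied).to_frame()
        div = div.join(rel.metadata[["treatment", "generation", "replicate"]])
        div.to_csv(out / "diversity.tsv", sep="\t", index_label="sample_id")
        community.shannon_pairwise_tests(rarefied).to_csv(
            out / "shannon_tests.tsv", sep="\t", index=False
        )

        stage = "ordination"
        dm = community.bray_curtis(rel)
        ord_res = community.pcoa(dm)
        with open(out / "ordination.tsv", "w") as fh:
            fh.write("# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in ord_res.eigenvalues) + "\n")
            fh.write("# percent_explained\t"
                     + "\t".join(f"{v:.6f}" for v in ord_res.percent_explained) + "\n")
            ord_res.coordinates.to_csv(fh, sep="\t", index_label="sample_id")

        stage = "permanova"
        perm = community.permanova(
            dm, rel.metadata, ["generation", "treatment"],
            n_perm=config.permanova_permutations, seed=config.seed,
        )
        perm.table.to_csv(out / "permanova.tsv", sep="\t", index_label="term")

        stage = "taxa"
        if taxonomy:
            community.aggregate_families(rel, taxonomy, config.top_k_families).data.to_csv(
                out / "family_abundance.tsv", sep="\t", index_label="sample_id"
            )
        community.heatmap_filter(rel, config.heatmap_threshold).data.to_csv(
            out / "heatmap_table.tsv", sep="\t", index_label="sample_id"
        )

        stage = "recovery"
        if truth is not None:
            recovery_report(results, truth, config.alpha).to_csv(
                out / "recovery.tsv", sep="\t", index_label="treatment"
            )
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %r", stage)
        raise

    stage = "manifest"
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_treatments": len(treatments),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def benjamini_hochberg(results: list[LsaResult]) -> list[LsaResult]:
    """Replace p-values by Benjamini-Hochberg adjusted values (optional mode)."""
    from dataclasses import replace
    from statsmodels.stats.multitest import multipletests

    if not results:
        return results
    p = np.array([r.p_value for r in results])
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [replace(r, p_value=float(q)) for r, q in zip(results, adj)]


def recovery_report(
    results_by_treatment: Mapping[str, Sequence[LsaResult]],
    truth: GroundTruth,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Precision / recall / sign accuracy of edge calls against planted truth.

    Recall is NA when nothing was planted; precision is NA when nothing was
    called.  Sign accuracy is computed over the recovered planted edges.
    """
    planted = {(a, b): s for a, b, s, _ in truth.true_edges}
    universe = {
        str(o) for frame in truth.latent_series.values() for o in frame.index
    } or {o for pair in planted for o in pair}
    rows = {}
    for t, results in results_by_treatment.items():
        known = {r.otu_a for r in results} | {r.otu_b for r in results}
        stray = (known - universe) if universe else set()
        if stray:
            raise ValidationError(f"results reference OTUs unknown to the ground truth: {sorted(stray)[:5]}")
        called = {(r.otu_a, r.otu_b): r.sign for r in results if r.p_value <= alpha}
        hits = set(called) & set(planted)
        recall = len(hits) / len(planted) if planted else float("nan")
        precision = (len(hits) / len(called)) if called else float("nan")
        if planted and not called:
            precision = float("nan")
        elif not planted and called:
            precision = 0.0
        sign_acc = (
            sum(called[e] == planted[e] for e in hits) / len(hits) if hits else float("nan")
        )
        rows[t] = {
            "n_planted": len(planted), "n_called": len(called), "n_recovered": len(hits),
            "recall": recall, "precision": precision, "sign_accuracy": sign_acc,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
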