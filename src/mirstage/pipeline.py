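"""End-to-end orchestration: preprocess -> DE -> profile -> network -> isomiR.

Every threshold actually applied is recorded in a JSON manifest together
with sha256 digests of the written artifacts, so identical config + seed
reproduce identical outputs for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import CountMatrix, cpm, filter_expressed, read_counts, tmm_factors
from . import differential as de
from . import profiles
from . import network as net
from . import isomir as iso

log = logging.getLogger("mirstage")

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    counts: str
    samples: str
    annotation: str | None = None
    offsets: str | None = None          # isomiR table TSV
    out_dir: str = "mirstage_out"
    min_cpm: float = 4.0
    fdr: float = 0.05
    large_fc: float = 5.0
    gammas: tuple[float, ...] = (1.0, 2.5)
    top_variant_fraction: float = 0.5
    shift_tolerance: int = 1
    min_fraction: float = 0.10
    min_reads: int = 50
    network_n_runs: int = 50
    cluster_tag: str = "Dlk1-Dio3"
    stage_order: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 < self.top_variant_fraction <= 1:
            raise ValueError("top_variant_fraction must be in (0, 1]")
        if self.min_cpm < 0 or self.min_fraction < 0 or self.min_reads < 1:
            raise ValueError("thresholds out of range")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: v for k, v in asdict(config).items()
                       if k not in ("counts", "samples", "annotation", "offsets",
                                    "out_dir")},
        "stages": {},
        "artifacts": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    # ---- preprocess -----------------------------------------------------
    try:
        cm = read_counts(config.counts, config.samples)
        filtered = filter_expressed(cm, min_cpm=config.min_cpm)
        norm = tmm_factors(filtered)
        log_expr = cpm(filtered, log2=True, prior=0.5,
                       lib_sizes=norm.effective_lib_sizes)
        artifacts["factors"] = _write(norm.factors.rename("tmm_factor").to_frame(),
                                      out / "tmm_factors.tsv", index_label="sample_id")
        artifacts["log2cpm"] = _write(log_expr, out / "log2cpm.tsv",
                                      index_label="mirna_id")
        record("preprocess", n_input=len(cm.mirna_ids),
               n_filtered=len(filtered.mirna_ids), ref_sample=norm.ref_sample)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"preprocess: {e}") from e

    # ---- differential expression ---------------------------------------
    try:
        stage_order = list(config.stage_order or pd.unique(filtered.stages))
        phi = de.estimate_dispersion(filtered).common_phi
        offs = np.log(norm.effective_lib_sizes.to_numpy(dtype=float))
        tables = [de.lrt_contrast(filtered, phi, a, b, offsets=offs)
                  for a, b in zip(stage_order[:-1], stage_order[1:])]
        for tab in tables:
            label = tab["contrast"].iloc[0].replace("->", "_to_").replace("|", "+")
            artifacts[f"de_{label}"] = _write(tab, out / f"de_{label}.tsv")
        summ = de.transition_summaries(tables, fdr_cut=config.fdr,
                                       large_fc=config.large_fc)
        artifacts["transition_summaries"] = _write(summ, out / "transition_summaries.tsv",
                                                   index=False)
        patterns = de.classify_temporal_pattern(tables, fdr_cut=config.fdr)
        artifacts["patterns"] = _write(patterns.to_frame(), out / "temporal_patterns.tsv",
                                       index_label="mirna_id")
        record("differential", phi=phi, n_transitions=len(tables),
               n_de_total=int(sum((t["fdr"] <= config.fdr).sum() for t in tables)))
    except Exception as e:  # noqa: BLE001
        raise StageError(f"differential: {e}") from e

    # ---- enrichment -----------------------------------------------------
    annotation = None
    if config.annotation:
        try:
            from .simulate import read_annotation

            annotation = read_annotation(config.annotation)
            first = tables[0]
            down = first.index[(first["fdr"] <= config.fdr) & (first["log2fc"] < 0)]
            table2x2, odds, pval = de.cluster_enrichment(
                down, annotation, first.index, config.cluster_tag)
            artifacts["enrichment"] = _write(table2x2, out / "cluster_enrichment.tsv")
            record("enrichment", cluster=config.cluster_tag, n_down=int(len(down)),
                   odds_ratio=float(odds) if np.isfinite(odds) else None, p=pval)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"enrichment: {e}") from e

    # ---- profile (PCA) --------------------------------------------------
    try:
        std = profiles.row_standardize(log_expr)
        top = profiles.top_variant(std, fraction=config.top_variant_fraction)
        pres = profiles.pca(top)
        artifacts["pca_scores"] = _write(pres.scores, out / "pca_scores.tsv",
                                         index_label="sample_id")
        artifacts["pca_loadings"] = _write(pres.loadings, out / "pca_loadings.tsv",
                                           index_label="mirna_id")
        record("profile", n_top=len(top),
               pc1_var=float(pres.variance_explained.iloc[0]))
    except Exception as e:  # noqa: BLE001
        raise StageError(f"profile: {e}") from e

    # ---- network --------------------------------------------------------
    try:
        sig = sorted(set().union(*[set(t.index[t["fdr"] <= config.fdr])
                                   for t in tables]))
        nodes = sig if len(sig) >= 10 else list(top.index)
        network = net.correlation_network(std.loc[std.index.intersection(nodes)])
        results, split_report = net.gamma_sweep(
            network, gammas=config.gammas, n_runs=config.network_n_runs,
            seed=config.seed)
        rep = results[0].representative
        sub_labels = {}
        for c in sorted(rep.assignment.unique()):
            members = rep.assignment.index[rep.assignment == c]
            if len(members) < 3:
                continue
            _, labels = net.submodules(std.loc[members], members, gamma=1.0,
                                       seed=config.seed, parent_label=str(c))
            sub_labels.update(labels.to_dict())
        part_df = rep.assignment.to_frame("module")
        part_df["submodule"] = [sub_labels.get(m, "") for m in part_df.index]
        artifacts["partition"] = _write(part_df, out / "partition.tsv",
                                        index_label="mirna_id")
        artifacts["gamma_split_report"] = out / "gamma_split_report.json"
        artifacts["gamma_split_report"].write_text(
            json.dumps(split_report.to_dict(orient="records"), indent=1))
        record("network", n_nodes=len(network.nodes), gamma=config.gammas[0],
               Q=rep.Q, n_modules=rep.n_communities)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"network: {e}") from e

    # ---- isomiR ---------------------------------------------------------
    if config.offsets:
        try:
            table = pd.read_csv(config.offsets, sep="\t")
            groups = filtered.stages if set(table["sample_id"]).issubset(
                set(filtered.sample_ids)) else None
            reports = iso.detect_switching(
                table, shift_tolerance=config.shift_tolerance,
                min_fraction=config.min_fraction, min_reads=config.min_reads,
                groups=groups)
            rows = [{"mirna_id": r.mirna_id, "switched": r.switched,
                     "max_shifted_fraction": max(r.shifted_fraction.values(), default=0.0),
                     "n_flagged_samples": len(r.flagged_samples)} for r in reports]
            artifacts["switch_reports"] = _write(pd.DataFrame(rows),
                                                 out / "isomir_switching.tsv", index=False)
            record("isomir", n_mirnas=len(reports),
                   n_switched=int(sum(r.switched for r in reports)))
        except Exception as e:  # noqa: BLE001
            raise StageError(f"isomir: {e}") from e

    manifest["artifacts"] = {k: {"path": str(p), "sha256": _digest(Path(p))}
                             for k, p in artifacts.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
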