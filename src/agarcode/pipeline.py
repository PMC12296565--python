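"""Orchestration: marker evaluation and panel classification runs.

Each run reads FASTA/TSV inputs, executes the relevant stages, and writes
plain-text reports (TSV, Newick, edge lists) plus a structured run log into
the output directory. Per-marker and per-sample failures are isolated and
logged; only hard configuration errors abort a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignio, distances, diagnostics, haplotypes, mjnet, njboot

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    inputs: dict[str, Path] = dataclasses.field(default_factory=dict)  # marker -> FASTA
    metadata: Path | None = None
    outdir: Path = Path("agarcode_out")
    bootstrap: int = 1000
    gap_threshold: float = 10.0
    epsilon: int = 0
    tau: float = 0.05
    key_path: Path | None = None
    pedigree_map: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap <= 0:
            raise ValueError("bootstrap must be positive")
        if self.gap_threshold <= 0:
            raise ValueError("gap threshold must be positive")
        if self.epsilon < 0 or not 0 <= self.tau <= 1:
            raise ValueError("epsilon must be >= 0 and tau in [0, 1]")

    def key(self) -> diagnostics.DiagnosticKey:
        if self.key_path is None:
            return diagnostics.default_key()
        return diagnostics.load_key(self.key_path)


def _write_log(cfg: RunConfig, stage: str, extra: dict) -> None:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": cfg.seed,
        "bootstrap": cfg.bootstrap,
        "gap_threshold": cfg.gap_threshold,
        "epsilon": cfg.epsilon,
        "tau": cfg.tau,
        **extra,
    }
    with open(cfg.outdir / f"{stage}.log.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def run_marker_evaluation(cfg: RunConfig) -> dict:
    """Marker evaluation: distances, gap verdicts, NJ+bootstrap, Table-2
    style haplotype summary. Per-marker failures are logged and skipped."""
    if not cfg.inputs:
        raise ValueError("no marker inputs configured")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"markers": {}, "warnings": []}
    alns: dict[str, alignio.LabeledAlignment] = {}
    for marker, path in cfg.inputs.items():
        try:
            aln = alignio.read_labeled_fasta(path, cfg.metadata, marker=marker)
        except Exception as err:  # noqa: BLE001 — isolate per-marker failure
            report["warnings"].append(f"{marker}: skipped ({err})")
            logger.warning("marker %s skipped: %s", marker, err)
            continue
        alns[marker] = aln
        safe = marker.replace("/", "_")
        dm = distances.distance_matrix(aln)
        dm.write_tsv(cfg.outdir / f"{safe}.distances.tsv")
        dm.write_phylip(cfg.outdir / f"{safe}.distances.phylip")
        summary = distances.summarize_distances(dm, list(aln.species), marker=marker)
        verdict = distances.barcode_gap(summary, cfg.gap_threshold)
        tree = njboot.bootstrap_support(aln, B=cfg.bootstrap, seed=cfg.seed)
        njboot.write_newick(tree, cfg.outdir / f"{safe}.nj.nwk")
        mono = njboot.species_monophyly(tree, dict(zip(aln.ids, aln.species)))
        pd.DataFrame(
            [
                {"species": sp, **vals}
                for sp, vals in mono.items()
            ]
        ).to_csv(cfg.outdir / f"{safe}.monophyly.tsv", sep="\t", index=False)
        report["markers"][marker] = {
            "n_sequences": aln.n,
            "intra_mean": summary.intra_mean,
            "inter_mean": summary.inter_mean,
            "inter_mean_pooled": summary.inter_mean_pooled,
            "gap_ratio": summary.gap_ratio,
            "gap_passes": verdict.passes,
            "gap_note": verdict.note,
            "monophyly": mono,
        }
    if alns:
        table = haplotypes.haplotype_summary(alns)
        table.to_csv(cfg.outdir / "haplotype_summary.tsv", sep="\t", index=False)
        report["haplotype_summary"] = table
        summary_rows = []
        for marker, stats in report["markers"].items():
            summary_rows.append(
                {
                    "marker": marker,
                    "intra_mean": stats["intra_mean"],
                    "inter_mean": stats["inter_mean"],
                    "gap_ratio": stats["gap_ratio"],
                    "gap_passes": stats["gap_passes"],
                }
            )
        pd.DataFrame(summary_rows).to_csv(cfg.outdir / "marker_summary.tsv", sep="\t", index=False)
    _write_log(cfg, "evaluate", {"markers": list(cfg.inputs), "warnings": report["warnings"]})
    return report


def project_panel(
    queries: dict[str, str], marker: str
) -> alignio.LabeledAlignment:
    """Project unaligned queries onto the marker reference frame.

    Each query is mapped by pairwise alignment; the result is an alignment
    over the reference columns, with columns missing from a query filled
    with ``-`` (masked downstream).
    """
    ref_len = diagnostics.reference_alignment(marker).length
    ids, seqs = [], []
    for sid, q in queries.items():
        colmap = diagnostics.map_to_reference(q, marker)
        row = "".join(colmap.get(c, "-") for c in range(1, ref_len + 1))
        ids.append(sid)
        seqs.append(row)
    return alignio.LabeledAlignment(
        marker=marker,
        ids=tuple(ids),
        seqs=tuple(seqs),
        species=tuple([None] * len(ids)),
        origin=tuple([None] * len(ids)),
    )


def run_classification(
    cfg: RunConfig,
    panel: list[tuple[alignio.SampleMetadata, str, str | None]] | None = None,
) -> dict:
    """Classify a panel of unknown samples against the diagnostic key.

    ``panel`` may be passed directly (programmatic use); otherwise the
    matK (and optional trnL-trnF) FASTA inputs are read, matching records
    by id. Writes a classification TSV, per-sample evidence JSON, and the
    Median-Joining network of the panel's matK haplotypes.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        if "matK" not in cfg.inputs:
            raise ValueError("classification requires a matK panel input")
        matk = alignio.read_labeled_fasta(cfg.inputs["matK"], cfg.metadata, marker="matK")
        trnl = None
        if "trnL-trnF" in cfg.inputs:
            trnl = alignio.read_labeled_fasta(cfg.inputs["trnL-trnF"], cfg.metadata, marker="trnL-trnF")
        trnl_by_id = dict(zip(trnl.ids, trnl.seqs)) if trnl else {}
        panel = [
            (
                alignio.SampleMetadata(id=rid, species=sp, origin=org),
                seq.replace("-", ""),
                trnl_by_id.get(rid, "").replace("-", "") or None,
            )
            for rid, seq, sp, org in zip(matk.ids, matk.seqs, matk.species, matk.origin)
        ]
    results, table, aggregate = diagnostics.classify_panel(
        panel, key=cfg.key(), pedigree_map=cfg.pedigree_map
    )
    table.to_csv(cfg.outdir / "classification.tsv", sep="\t", index=False)
    with open(cfg.outdir / "classification_evidence.json", "w") as fh:
        json.dump([dataclasses.asdict(r) for r in results], fh, indent=2)
    note = None
    if all(t is None for _, _, t in panel):
        note = "no trnL-trnF sequences supplied: origin refinement skipped"

    # network over the panel's matK haplotypes
    network_summary = None
    try:
        projected = project_panel({m.id: q for m, q, _ in panel}, "matK")
        hap_table = haplotypes.collapse_haplotypes(projected, "all", marker="matK")
        if hap_table.n_haplotypes >= 2:
            net = mjnet.mj_network(hap_table, epsilon=cfg.epsilon)
            mjnet.export_network(net, cfg.outdir / "panel_network.tsv", "tsv")
            network_summary = {
                "n_haplotypes": hap_table.n_haplotypes,
                "n_nodes": len(net.nodes),
                "total_length": net.total_length(),
            }
    except Exception as err:  # noqa: BLE001
        logger.warning("panel network skipped: %s", err)
    _write_log(cfg, "classify", {"aggregate": aggregate, "note": note})
    return {
        "results": results,
        "table": table,
        "aggregate": aggregate,
        "network": network_summary,
        "note": note,
    }
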