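"""End-to-end screen pipeline: simulate/ingest → ψ → Δψ → calls → clusters.

The driver composes the quantification, calling, clustering and enrichment
stages in screen order and writes one TSV per stage plus a run log.
Re-running with an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import build_dpsi_matrix, cut_k, hierarchical_cluster
from .config import PipelineConfig
from .electropherogram import (
    AmpliconAssignment,
    PeakRecord,
    SizeCalibration,
    apply_calibration,
    assign_amplicons,
    detect_peaks,
    quantify_molar,
)
from .enrichment import read_gmt, test_overrepresentation
from .io import write_table
from .psi import (
    PSI_COLUMNS,
    call_changes,
    compute_delta_psi,
    compute_psi,
    consensus_distribution,
    summarize_screen,
)
from .synthetic import (
    AseDefinition,
    Sample,
    catalog_to_frame,
    default_ladder,
    frame_to_catalog,
    generate_ase_catalog,
    generate_samples,
    generate_truth,
    simulate_peak_table,
    synthesize_trace,
)

__all__ = [
    "quantify_peak_table",
    "quantify_traces",
    "run_pipeline",
    "DEFAULT_MIN_HEIGHT",
    "DEFAULT_MIN_SEPARATION",
]

logger = logging.getLogger(__name__)

#: default peak-detection floor, signal units (≈ 2× the default trace SNR floor)
DEFAULT_MIN_HEIGHT = 100.0
#: default minimum apex separation, migration-time units (≈ 6 peak widths)
DEFAULT_MIN_SEPARATION = 0.12


def _psi_from_assignment(assignment: AmpliconAssignment, min_total: float) -> float:
    inc = quantify_molar(assignment.inclusion) if assignment.inclusion else None
    exc = quantify_molar(assignment.exclusion) if assignment.exclusion else None
    return compute_psi(inc, exc, min_total=min_total)


def quantify_peak_table(
    peaks: pd.DataFrame,
    catalog: Sequence[AseDefinition],
    rel_tol: float = 0.10,
    min_total: float = 0.05,
) -> pd.DataFrame:
    """ψ per sample × event from a pre-quantified peak table.

    ``peaks`` follows the peaks schema (cell_line, condition, batch_day,
    ase_id, amplicon, called_size_bp, area).  Peaks are re-assigned to the
    catalog's expected amplicons by size — the ``amplicon`` column is what
    the simulator planted, not what the analysis trusts.
    """
    by_id = {a.ase_id: a for a in catalog}
    rows = []
    for (cl, cond, day, ase_id), grp in peaks.groupby(
        ["cell_line", "condition", "batch_day", "ase_id"], sort=True
    ):
        ase = by_id[ase_id]
        records = [
            PeakRecord(apex_time=0.0, area=float(r.area), height=float(r.area),
                       called_size_bp=float(r.called_size_bp))
            for r in grp.itertuples(index=False)
        ]
        assignment = assign_amplicons(
            records, ase.size_inclusion_bp, ase.size_exclusion_bp, rel_tol=rel_tol
        )
        rows.append(
            {
                "ase_id": ase_id,
                "cell_line": cl,
                "condition": cond,
                "batch_day": int(day),
                "psi": _psi_from_assignment(assignment, min_total),
            }
        )
    return pd.DataFrame(rows, columns=PSI_COLUMNS)


def quantify_traces(
    traces: Iterable[tuple[Sample, AseDefinition, "Trace"]],
    calibration: Optional[SizeCalibration] = None,
    rel_tol: float = 0.10,
    min_total: float = 0.05,
    min_height: float = DEFAULT_MIN_HEIGHT,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> pd.DataFrame:
    """ψ per sample × event from raw electropherograms (one well per event)."""
    cal = calibration or default_ladder()
    rows = []
    for sample, ase, trace in traces:
        peaks = apply_calibration(detect_peaks(trace, min_height, min_separation), cal)
        assignment = assign_amplicons(
            peaks, ase.size_inclusion_bp, ase.size_exclusion_bp, rel_tol=rel_tol
        )
        rows.append(
            {
                "ase_id": ase.ase_id,
                "cell_line": sample.cell_line,
                "condition": sample.condition,
                "batch_day": sample.batch_day,
                "psi": _psi_from_assignment(assignment, min_total),
            }
        )
    return pd.DataFrame(rows, columns=PSI_COLUMNS).sort_values(
        ["ase_id", "cell_line", "condition", "batch_day"]
    ).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full screen and write all stage tables to ``config.outdir``.

    Outputs: catalog.tsv, truth.tsv + kd.tsv (simulated runs), peaks.tsv,
    psi.tsv, delta_psi.tsv, calls.tsv, summary.tsv, matrix.tsv,
    clusters.tsv, enrichment.tsv (when a GMT is configured) and run_log.txt.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"spliceshift {__version__} (python {sys.version.split()[0]}, "
        f"numpy {np.__version__}, pandas {pd.__version__})",
        f"seed={config.seed} threshold={config.threshold} rel_tol={config.rel_tol} "
        f"linkage={config.linkage} lenient={config.lenient}",
    ]

    # --- inputs: simulate or ingest -------------------------------------
    if config.catalog_path:
        catalog = frame_to_catalog(pd.read_csv(config.catalog_path, sep="\t"))
        log_lines.append(f"catalog: {config.catalog_path} ({len(catalog)} events)")
    else:
        catalog = generate_ase_catalog(config.n_ases, seed=config.seed)
        log_lines.append(f"catalog: simulated, {len(catalog)} events")
    write_table(catalog_to_frame(catalog), outdir / "catalog.tsv", schema="catalog")

    if config.peaks_path:
        peaks = pd.read_csv(config.peaks_path, sep="\t")
        log_lines.append(f"peaks: {config.peaks_path}")
        psi_table = quantify_peak_table(
            peaks, catalog, rel_tol=config.rel_tol, min_total=config.min_total
        )
    else:
        truth = generate_truth(
            catalog,
            cell_lines=config.cell_lines,
            prop_null=config.prop_null,
            effect_mean_abs=config.effect_mean_abs,
            effect_sd=config.effect_sd,
            discordant_rate=config.discordant_rate,
            response_rate=config.response_rate,
            seed=config.seed + 1,
        )
        write_table(truth.effects, outdir / "truth.tsv", schema="truth")
        write_table(truth.kd, outdir / "kd.tsv", schema="kd")
        samples = generate_samples(config.cell_lines)
        if config.use_traces:
            rng = np.random.default_rng(config.seed + 2)
            trace_iter = (
                (s, ase, synthesize_trace(s, [ase], truth, config.noise, rng=rng))
                for s in samples
                for ase in catalog
            )
            psi_table = quantify_traces(
                trace_iter, rel_tol=config.rel_tol, min_total=config.min_total
            )
            log_lines.append("quantification: synthetic traces")
        else:
            peaks = simulate_peak_table(
                catalog, truth, samples, noise=config.noise, seed=config.seed + 2
            )
            write_table(peaks, outdir / "peaks.tsv", schema="peaks")
            psi_table = quantify_peak_table(
                peaks, catalog, rel_tol=config.rel_tol, min_total=config.min_total
            )
            log_lines.append("quantification: simulated peak table")

    # --- ψ → Δψ → calls → summary ---------------------------------------
    write_table(psi_table, outdir / "psi.tsv", schema="psi")
    delta = compute_delta_psi(psi_table)
    write_table(delta, outdir / "delta_psi.tsv", schema="delta_psi")
    calls = call_changes(delta, threshold=config.threshold, lenient=config.lenient)
    write_table(calls, outdir / "calls.tsv", schema="calls")
    summary = summarize_screen(calls, n_ases=len(catalog))
    summary.to_frame().to_csv(outdir / "summary.tsv", sep="\t", index=False)
    log_lines.append(
        f"changed: {summary.n_changed_any}/{summary.n_ases} "
        f"({summary.pct_changed_any_str}) events in >=1 cell line"
    )
    if calls["cell_line"].nunique() >= 2:
        consensus = consensus_distribution(calls)
        log_lines.append(f"consensus multiplicities: {consensus.histogram}")

    # --- clustering ------------------------------------------------------
    genes = {a.ase_id: a.gene for a in catalog}
    if calls["changed"].any() and calls.loc[calls["changed"], "ase_id"].nunique() >= 2:
        matrix = build_dpsi_matrix(calls, genes=genes, threshold=config.threshold)
        row_tree = hierarchical_cluster(matrix.values, linkage_method=config.linkage)
        col_tree = hierarchical_cluster(matrix.values.T, linkage_method=config.linkage)
        two_way = matrix.values.loc[row_tree.leaf_order(), col_tree.leaf_order()]
        out = two_way.copy()
        out.insert(0, "gene", [matrix.genes[a] for a in out.index])
        out.index.name = "ase_id"
        out.reset_index().to_csv(outdir / "matrix.tsv", sep="\t", index=False, na_rep="NA")
        clusters = cut_k(row_tree, k=min(2, row_tree.n_leaves)).rename_axis("ase_id")
        clusters.reset_index().to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        log_lines.append(
            f"clustering: {row_tree.n_leaves} changed events, {config.linkage} linkage"
        )
    else:
        log_lines.append("clustering: skipped (<2 changed events)")

    # --- enrichment -------------------------------------------------------
    if config.gmt_path:
        collection = read_gmt(config.gmt_path)
        changed_ases = set(calls.loc[calls["changed"], "ase_id"])
        changed_genes = {genes[a] for a in changed_ases}
        universe = set(genes.values())
        enr = test_overrepresentation(changed_genes, universe, collection)
        write_table(enr, outdir / "enrichment.tsv", schema="enrichment")
        log_lines.append(f"enrichment: {len(enr)} sets tested against {len(universe)} genes")

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir
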