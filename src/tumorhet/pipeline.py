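"""End-to-end orchestration: simulate -> analyze -> recover.

``run_simulate`` writes a synthetic cohort (VCFs, FASTA, metadata, CNV
tables, ground truth).  ``run_analyze`` runs the full analysis on a cohort
directory (simulated or user-provided in the same flat schema): filtration
cascades, truncal/private partition and clone trees, per-branch signature
exposures, smoking metrics, LOH calls, CNV candidates and heterogeneity,
and the germline-repair association.  ``run_recover`` scores analysis
outputs against the ground truth.  Every stage records its record counts in
a JSON manifest so exclusions are auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import allelic, clonal, filters, signatures, stats, vcfio
from .exceptions import ConfigError, InsufficientDataError, SchemaError
from .synthetic import GroundTruth, SimConfig, simulate_cohort, write_cohort

LOH_LINK_WINDOW = 2000  # bp within which an LOH-called het flags a somatic variant


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_simulate(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> dict:
    """Simulate a cohort and serialize it; returns the run manifest."""
    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    if seed is not None:
        config.seed = seed
    out_dir = Path(out_dir)
    cohort, truth, refmap = simulate_cohort(config)
    counts = write_cohort(cohort, truth, refmap, config, out_dir)
    manifest = {
        "stage": "simulate",
        "seed": config.seed,
        "config": config.to_dict(),
        "patients": counts,
        "n_patients": len(cohort),
    }
    _write_manifest(out_dir, manifest)
    return manifest


def _is_het_in_germline(variant, min_depth: int = 15) -> bool:
    support = variant.per_region_support.get("germline")
    if support is None:
        return False
    alt_reads, total = support
    if total < min_depth:
        return False
    vaf = alt_reads / total
    return 0.2 <= vaf <= 0.8


def _analyze_patient(
    pid: str,
    pdir: Path,
    region_ids: list[str],
    cellularities: dict[str, float],
    pack_years: Optional[float],
    refmap: dict[str, str],
    catalog,
    driver_genes: set[str],
    repair_genes: set[str],
    callable_mb: float,
    bin_size: int,
    out_pdir: Path,
) -> dict:
    out_pdir.mkdir(parents=True, exist_ok=True)
    somatic = vcfio.read_vcf(pdir / "somatic.vcf", region_ids)
    germline = vcfio.read_vcf(pdir / "germline.vcf", ["germline", *region_ids])

    # --- clonal partition and tree ---
    assignments, n_dropped = clonal.partition_variants(somatic, region_ids)
    tree = clonal.build_tree(somatic, assignments, region_ids)
    (out_pdir / "tree.nwk").write_text(clonal.to_newick(tree) + "\n")
    pd.DataFrame(clonal.to_edge_rows(tree)).to_csv(
        out_pdir / "tree_edges.tsv", sep="\t", index=False
    )
    branch_counts = clonal.branch_mutation_counts(tree)
    n_classified = sum(branch_counts.values())

    # --- signatures per branch + smoking metrics off the trunk ---
    fits = signatures.branch_signatures(tree, refmap, catalog)
    exposure_rows = []
    for branch, fit in sorted(fits.items()):
        if fit is None:
            continue
        for name, fraction, exposure in zip(fit.signature_names, fit.fractions, fit.exposures):
            exposure_rows.append(
                {
                    "patient_id": pid,
                    "branch": branch,
                    "signature": name,
                    "fraction": round(float(fraction), 6),
                    "exposure": round(float(exposure), 2),
                    "n_snvs": fit.n_mutations,
                    "low_confidence": fit.low_confidence,
                }
            )
    pd.DataFrame(
        exposure_rows,
        columns=[
            "patient_id", "branch", "signature", "fraction",
            "exposure", "n_snvs", "low_confidence",
        ],
    ).to_csv(out_pdir / "exposures.tsv", sep="\t", index=False)

    trunk_fit = fits.get("truncal")
    if trunk_fit is not None:
        metrics = signatures.smoking_metrics(trunk_fit, pack_years)
        smoking_fraction = metrics.smoking_fraction
        smoking_count = metrics.smoking_variant_count
        smoking_per_py = metrics.smoking_variants_per_py
    else:
        smoking_fraction = smoking_count = smoking_per_py = None

    burden = filters.mutation_burden(n_classified, callable_mb)

    # --- LOH on germline-het sites, per region ---
    hets = [v for v in germline if _is_het_in_germline(v)]
    loh_rows = []
    loh_sites_by_region: dict[str, list[int]] = {r: [] for r in region_ids}
    for region in region_ids:
        counts = []
        keys = []
        for v in hets:
            support = v.per_region_support.get(region)
            if support is None:
                continue
            counts.append(support)
            keys.append((v.chrom, v.pos))
        calls = allelic.detect_loh(counts, cellularities[region], keys=keys)
        for call in calls:
            chrom, pos = call.key
            loh_rows.append(
                {
                    "patient_id": pid,
                    "region_id": region,
                    "chrom": chrom,
                    "pos": pos,
                    "status": call.status,
                    "llr": round(call.log_likelihood_ratio, 3),
                }
            )
            if call.status == "LOH":
                loh_sites_by_region[region].append(pos)
    pd.DataFrame(
        loh_rows, columns=["patient_id", "region_id", "chrom", "pos", "status", "llr"]
    ).to_csv(out_pdir / "loh.tsv", sep="\t", index=False)

    # --- filtration cascades ---
    driver_decisions = filters.somatic_driver_filter(somatic, driver_genes)
    loh_flags = {}
    for v in somatic:
        flagged = False
        for region in region_ids:
            support = v.per_region_support.get(region)
            if support is None or clonal.call_presence(*support) != clonal.PRESENT:
                continue
            if any(abs(v.pos - pos) <= LOH_LINK_WINDOW for pos in loh_sites_by_region[region]):
                flagged = True
                break
        loh_flags[v.key] = flagged
    lof_decisions = filters.somatic_lof_loh_filter(somatic, loh_flags)
    germline_decisions = filters.germline_repair_filter(germline, repair_genes)

    oncoprint_rows = []
    for d in driver_decisions:
        if not d.passed:
            continue
        v = d.variant
        row = {
            "patient_id": pid,
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "impact": v.impact,
        }
        for region in region_ids:
            support = v.per_region_support.get(region, (0, 0))
            row[region] = clonal.call_presence(*support)
        oncoprint_rows.append(row)
    pd.DataFrame(
        oncoprint_rows,
        columns=["patient_id", "gene", "chrom", "pos", "impact", *region_ids],
    ).to_csv(out_pdir / "oncoprint.tsv", sep="\t", index=False)

    pd.DataFrame(filters.decisions_to_rows(lof_decisions)).to_csv(
        out_pdir / "lof_loh_decisions.tsv", sep="\t", index=False
    )
    pd.DataFrame(filters.decisions_to_rows(germline_decisions)).to_csv(
        out_pdir / "germline_decisions.tsv", sep="\t", index=False
    )
    germline_mutant = any(d.passed for d in germline_decisions)

    # --- CNV candidates and heterogeneity ---
    profiles = {}
    for region in region_ids:
        seg_path = pdir / f"cnv_{region}.tsv"
        if seg_path.exists():
            profiles[region] = vcfio.read_segments(seg_path)
    candidate_rows = []
    for region, profile in profiles.items():
        for seg in allelic.cnv_candidate_filter(profile):
            candidate_rows.append(
                {
                    "patient_id": pid,
                    "region_id": region,
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "copy_number": seg.copy_number,
                }
            )
    pd.DataFrame(
        candidate_rows,
        columns=["patient_id", "region_id", "chrom", "start", "end", "copy_number"],
    ).to_csv(out_pdir / "cnv_candidates.tsv", sep="\t", index=False)
    if len(profiles) >= 2:
        matrix = allelic.cnv_heterogeneity(profiles, bin_size=bin_size)
        matrix.to_csv(out_pdir / "cnv_distance.tsv", sep="\t")

    return {
        "patient_id": pid,
        "n_somatic_read": len(somatic),
        "n_classified": n_classified,
        "n_dropped": n_dropped,
        "n_germline_read": len(germline),
        "branch_counts": branch_counts,
        "metrics": {
            "n_somatic": n_classified,
            "burden_per_mb": burden,
            "hypermutated": filters.classify_hypermutated(burden),
            "smoking_fraction": smoking_fraction,
            "smoking_variant_count": smoking_count,
            "smoking_variants_per_py": smoking_per_py,
            "pack_years": pack_years,
            "germline_mutant": germline_mutant,
            "n_germline_passing": sum(d.passed for d in germline_decisions),
        },
    }


def run_analyze(
    cohort_dir: str | Path,
    out_dir: str | Path,
    drivers: Optional[str | Path] = None,
    repair_genes: Optional[str | Path] = None,
    catalog: Optional[str | Path] = None,
    bin_size: int = 5000,
) -> dict:
    """Analyze a cohort directory; returns the run manifest.

    ``bin_size`` is the CNV-heterogeneity raster bin; the default suits the
    synthetic 100 kb reference (use ~1 Mb for genome-scale segment tables).
    """
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metadata_path = cohort_dir / "metadata.tsv"
    if not metadata_path.exists():
        raise SchemaError(f"cohort directory {cohort_dir} has no metadata.tsv")
    metadata = pd.read_csv(metadata_path, sep="\t")
    required_cols = {"patient_id", "region_id", "cellularity"}
    if not required_cols.issubset(metadata.columns):
        raise SchemaError(f"metadata.tsv must have columns {sorted(required_cols)}")

    refmap = vcfio.read_fasta(cohort_dir / "reference.fa")
    catalog_obj = vcfio.load_catalog(catalog) if catalog else vcfio.default_catalog()
    driver_set = vcfio.load_gene_list(drivers) if drivers else vcfio.default_gene_list("drivers")
    repair_set = (
        vcfio.load_gene_list(repair_genes) if repair_genes else vcfio.default_gene_list("repair")
    )
    config_path = cohort_dir / "config.yaml"
    callable_mb = 100.0
    if config_path.exists():
        callable_mb = float(SimConfig.from_yaml(config_path).callable_mb)

    patient_summaries = []
    metric_rows = []
    skipped = []
    for pid, group in metadata.groupby("patient_id", sort=True):
        pdir = cohort_dir / "patients" / str(pid)
        if not (pdir / "somatic.vcf").exists():
            skipped.append(str(pid))
            continue
        region_ids = list(group["region_id"])
        cellularities = dict(zip(group["region_id"], group["cellularity"].astype(float)))
        pack_years = (
            float(group["pack_years"].iloc[0]) if "pack_years" in group.columns else None
        )
        summary = _analyze_patient(
            str(pid),
            pdir,
            region_ids,
            cellularities,
            pack_years,
            refmap,
            catalog_obj,
            driver_set,
            repair_set,
            callable_mb,
            bin_size,
            out_dir / "patients" / str(pid),
        )
        patient_summaries.append(summary)
        metric_rows.append({"patient_id": str(pid), **summary["metrics"]})

    metric_table = pd.DataFrame(metric_rows)
    metric_table.to_csv(out_dir / "patient_metrics.tsv", sep="\t", index=False)

    # --- cohort association: germline repair status vs smoking metrics ---
    comparisons = []
    association_rows = []
    if len(metric_table):
        for metric, test_kind in [
            ("smoking_fraction", stats.WELCH),
            ("burden_per_mb", stats.WELCH),
            ("smoking_variants_per_py", stats.STUDENT),
        ]:
            try:
                comparison = stats.compare_by_germline_status(metric_table, metric, test_kind)
            except (InsufficientDataError, ValueError) as exc:
                association_rows.append(
                    {"metric": metric, "test_kind": test_kind, "error": str(exc)}
                )
                continue
            comparisons.append(comparison)
            association_rows.append(
                {
                    "metric": metric,
                    "test_kind": test_kind,
                    "n_mutant": comparison.group_sizes[0],
                    "n_wildtype": comparison.group_sizes[1],
                    "mean_mutant": round(comparison.means[0], 6),
                    "mean_wildtype": round(comparison.means[1], 6),
                    "t": round(comparison.t_statistic, 6),
                    "df": round(comparison.degrees_of_freedom, 4),
                    "p_value": comparison.p_value,
                    "n_excluded": comparison.n_excluded,
                }
            )
    pd.DataFrame(association_rows).to_csv(out_dir / "association.tsv", sep="\t", index=False)
    (out_dir / "association.txt").write_text(
        stats.comparison_report(comparisons) + "\n" if comparisons else "no comparisons\n"
    )

    manifest = {
        "stage": "analyze",
        "cohort_dir": str(cohort_dir),
        "n_patients": len(patient_summaries),
        "skipped_patients": skipped,
        "patients": {
            s["patient_id"]: {
                "n_somatic_read": s["n_somatic_read"],
                "n_classified": s["n_classified"],
                "n_dropped": s["n_dropped"],
                "n_germline_read": s["n_germline_read"],
            }
            for s in patient_summaries
        },
    }
    _write_manifest(out_dir, manifest)
    return manifest


def run_recover(analysis_dir: str | Path, cohort_dir: str | Path) -> pd.DataFrame:
    """Score analysis outputs against the cohort's ground truth.

    Returns (and writes) a table of truth-vs-estimate rows covering truncal
    fraction, trunk tobacco exposure, segment-level LOH detection, and the
    direction of the germline association.
    """
    analysis_dir = Path(analysis_dir)
    cohort_dir = Path(cohort_dir)
    try:
        truth = GroundTruth.read(cohort_dir / "truth")
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot load ground truth: {exc}") from exc

    rows = []
    for pid, group in truth.variants.groupby("patient_id", sort=True):
        true_truncal = float((group["branch"] == "truncal").mean())
        edges = pd.read_csv(
            analysis_dir / "patients" / str(pid) / "tree_edges.tsv", sep="\t"
        )
        total = edges["mutations"].sum()
        trunk = edges.loc[edges["child"] == "truncal", "mutations"].sum()
        est_truncal = float(trunk / total) if total else float("nan")
        rows.append(
            {
                "patient_id": pid,
                "quantity": "truncal_fraction",
                "truth": round(true_truncal, 6),
                "estimate": round(est_truncal, 6),
                "abs_error": round(abs(est_truncal - true_truncal), 6),
            }
        )

        true_tobacco = truth.exposures.query(
            "patient_id == @pid and branch == 'truncal' and signature == 'tobacco-like'"
        )["fraction"]
        fitted = pd.read_csv(analysis_dir / "patients" / str(pid) / "exposures.tsv", sep="\t")
        est_tobacco = fitted.query("branch == 'truncal' and signature == 'tobacco-like'")[
            "fraction"
        ]
        if len(true_tobacco) and len(est_tobacco):
            t_val, e_val = float(true_tobacco.iloc[0]), float(est_tobacco.iloc[0])
            rows.append(
                {
                    "patient_id": pid,
                    "quantity": "trunk_tobacco_fraction",
                    "truth": round(t_val, 6),
                    "estimate": round(e_val, 6),
                    "abs_error": round(abs(e_val - t_val), 6),
                }
            )

    # segment-level LOH recovery
    loh_truth = truth.cnv
    n_true_pos = n_detected = n_true_neg = n_false_pos = 0
    for (pid, region), group in loh_truth.groupby(["patient_id", "region_id"], sort=True):
        loh_path = analysis_dir / "patients" / str(pid) / "loh.tsv"
        if not loh_path.exists():
            continue
        calls = pd.read_csv(loh_path, sep="\t")
        calls = calls[calls["region_id"] == region]
        for _, seg in group.iterrows():
            in_seg = calls[(calls["pos"] >= seg["start"]) & (calls["pos"] <= seg["end"])]
            informative = in_seg[in_seg["status"] != "indeterminate"]
            if len(informative) < 3:
                continue
            detected = (informative["status"] == "LOH").mean() >= 0.5
            if bool(seg["loh"]):
                n_true_pos += 1
                n_detected += int(detected)
            else:
                n_true_neg += 1
                n_false_pos += int(detected)
    if n_true_pos:
        rows.append(
            {
                "patient_id": "cohort",
                "quantity": "loh_segment_sensitivity",
                "truth": 1.0,
                "estimate": round(n_detected / n_true_pos, 6),
                "abs_error": round(1.0 - n_detected / n_true_pos, 6),
            }
        )
    if n_true_neg:
        rows.append(
            {
                "patient_id": "cohort",
                "quantity": "loh_segment_false_positive_rate",
                "truth": 0.0,
                "estimate": round(n_false_pos / n_true_neg, 6),
                "abs_error": round(n_false_pos / n_true_neg, 6),
            }
        )

    # association direction
    patients_truth = truth.patients
    if patients_truth["germline_mutant"].nunique() == 2:
        true_dir = (
            patients_truth.loc[patients_truth["germline_mutant"], "tobacco_fraction"].mean()
            > patients_truth.loc[~patients_truth["germline_mutant"], "tobacco_fraction"].mean()
        )
        assoc_path = analysis_dir / "association.tsv"
        est_dir = None
        if assoc_path.exists():
            assoc = pd.read_csv(assoc_path, sep="\t")
            row = assoc[assoc["metric"] == "smoking_fraction"]
            if len(row) and "mean_mutant" in row.columns and row["mean_mutant"].notna().all():
                est_dir = bool(row["mean_mutant"].iloc[0] > row["mean_wildtype"].iloc[0])
        if est_dir is not None:
            rows.append(
                {
                    "patient_id": "cohort",
                    "quantity": "germline_tobacco_direction_match",
                    "truth": float(true_dir),
                    "estimate": float(est_dir),
                    "abs_error": float(true_dir != est_dir),
                }
            )

    report = pd.DataFrame(rows, columns=["patient_id", "quantity", "truth", "estimate", "abs_error"])
    report.to_csv(analysis_dir / "recovery.tsv", sep="\t", index=False)
    return report
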