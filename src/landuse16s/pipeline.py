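"""End-to-end orchestration: simulate -> demux -> trim -> classify -> stats.

The in-memory entry points (:func:`simulate_dataset`, :func:`analyze`,
:func:`run_study`) are what tests and analysis drivers use; the file-based
:func:`run_simulate` / :func:`run_pipeline` wrap them behind the on-disk
formats (FASTA/FASTQ/TSV) and are what the CLI exposes.  Every stage logs
one conservation line (input = output + discarded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .classify import PairClassifier, RankThresholds, normalize, tabulate
from .reads import (
    ReadPair,
    TrimPolicy,
    count_trimmed_pairs,
    demultiplex,
    read_fastq_pairs,
    trim_pairs,
    write_fastq_pairs,
)
from .soil import annotate_soil_table
from .stats import (
    AnalysisConfig,
    abundance_filter,
    fold_change,
    signature_genera,
    spearman,
    venn_partition,
)
from .taxonomy import RANKS, ReferenceDatabase, parse_reference_fasta, write_reference_fasta

log = logging.getLogger("landuse16s")



@dataclass
class SimulatedDataset:
    config: sim.SimulationConfig
    db: ReferenceDatabase
    soils: list[sim.SoilSample]
    barcodes: dict[str, str]  # barcode -> sample
    pairs: list[ReadPair]
    truth: dict[str, str]

    @property
    def sheet(self) -> pd.DataFrame:
        return sim.sample_sheet(self.soils, self.barcodes)

    @property
    def soil_df(self) -> pd.DataFrame:
        return sim.soil_table(self.soils)


def simulate_dataset(config: sim.SimulationConfig) -> SimulatedDataset:
    """Generate the complete synthetic study for one seed."""
    db = sim.generate_reference_db(config)
    soils = sim.generate_soil_covariates(config)
    barcodes = sim.generate_barcodes(config, [s.sample for s in soils])
    bc_by_sample = {s: b for b, s in barcodes.items()}
    pairs: list[ReadPair] = []
    truth: dict[str, str] = {}
    for soil in soils:
        profile = sim.generate_community(soil, config)
        p, t = sim.generate_reads(profile, db, config, bc_by_sample[soil.sample])
        pairs.extend(p)
        truth.update(t)
    log.info("simulate: %d samples, %d read pairs", len(soils), len(pairs))
    return SimulatedDataset(config, db, soils, barcodes, pairs, truth)


@dataclass
class StudyResults:
    demux_report: pd.DataFrame
    denominators: dict[str, int]
    assignments: list
    counts_by_rank: dict[str, pd.DataFrame]
    relabund_genus: pd.DataFrame
    soil: pd.DataFrame
    correlations: pd.DataFrame
    abundant_by_site: dict[str, set[str]]
    venn: tuple[dict[str, int], float] | None
    signatures: pd.DataFrame
    fold_changes: pd.DataFrame


def analyze(
    db: ReferenceDatabase,
    pairs: list[ReadPair],
    barcode_map: dict[str, str],
    sheet: pd.DataFrame,
    soil_df: pd.DataFrame,
    trim_policy: TrimPolicy | None = None,
    thresholds: RankThresholds | None = None,
    analysis: AnalysisConfig | None = None,
) -> StudyResults:
    """The full analysis chain downstream of simulation / input loading."""
    trim_policy = trim_policy or TrimPolicy()
    analysis = analysis or AnalysisConfig()

    # demultiplex + trim; surviving-pair counts are the denominators
    per_sample, discarded = demultiplex(pairs, barcode_map)
    assigned = sum(len(v) for v in per_sample.values())
    log.info("demux: %d in = %d assigned + %d discarded", len(pairs), assigned, discarded)
    trimmed = {s: trim_pairs(ps, trim_policy) for s, ps in per_sample.items()}
    denominators = count_trimmed_pairs(trimmed)
    n_trimmed = sum(denominators.values())
    log.info("trim: %d in = %d surviving + %d rejected", assigned, n_trimmed, assigned - n_trimmed)
    demux_report = pd.DataFrame(
        {
            "sample": list(per_sample),
            "assigned": [len(per_sample[s]) for s in per_sample],
            "trimmed_pairs": [denominators[s] for s in per_sample],
        }
    ).set_index("sample")

    # classify and tabulate at every rank
    clf = PairClassifier(db, thresholds)
    assignments = clf.classify_pairs(trimmed)
    status = pd.Series([a.status for a in assignments]).value_counts().to_dict()
    log.info("classify: %d pairs by status %s", len(assignments), status)
    samples = list(sheet.index)
    counts_by_rank = {r: tabulate(assignments, r, samples) for r in RANKS}
    relabund = normalize(counts_by_rank["genus"], denominators)

    soil = annotate_soil_table(soil_df) if "nh3" not in soil_df.columns else soil_df.copy()
    stats_out = landuse_statistics(
        counts_by_rank["genus"], relabund, denominators, sheet, soil, analysis
    )

    return StudyResults(
        demux_report=demux_report,
        denominators=denominators,
        assignments=assignments,
        counts_by_rank=counts_by_rank,
        relabund_genus=relabund,
        soil=soil,
        **stats_out,
    )


def landuse_statistics(
    counts_genus: pd.DataFrame,
    relabund: pd.DataFrame,
    denominators: dict[str, int],
    sheet: pd.DataFrame,
    soil: pd.DataFrame,
    analysis: AnalysisConfig | None = None,
) -> dict:
    """Correlations, abundance filter, Venn, signatures and fold changes."""
    analysis = analysis or AnalysisConfig()
    samples = list(relabund.columns)
    corr_rows = []
    sites = sorted(sheet["site"].unique())
    for site in sites:
        site_samples = [s for s in samples if sheet.loc[s, "site"] == site]
        y_by_cov = {
            "land_use": sheet.loc[site_samples, "land_use"].to_numpy(dtype=float),
            "ph": soil.loc[site_samples, "ph"].to_numpy(dtype=float),
            "nh3": soil.loc[site_samples, "nh3"].to_numpy(dtype=float),
        }
        for genus in relabund.index:
            x = relabund.loc[genus, site_samples].to_numpy(dtype=float)
            if np.all(x == x[0]):
                continue  # undefined correlation at this site
            for cov, y in y_by_cov.items():
                rho, p = spearman(x, y)
                corr_rows.append(
                    {"site": site, "genus": genus, "covariate": cov, "rho": rho,
                     "p": p, "n": len(x)}
                )
    correlations = pd.DataFrame(
        corr_rows, columns=["site", "genus", "covariate", "rho", "p", "n"]
    )

    counts_by_site = {
        site: counts_genus[[s for s in samples if sheet.loc[s, "site"] == site]]
        for site in sites
    }
    abundant = abundance_filter(counts_by_site, denominators, analysis.abundance_floor)
    venn = venn_partition(abundant) if len(sites) == 3 else None

    landuse_corr = {
        site: correlations[
            (correlations["site"] == site) & (correlations["covariate"] == "land_use")
        ].set_index("genus")[["rho", "p"]]
        for site in sites
    }
    signatures = signature_genera(landuse_corr, abundant, analysis)

    fold_rows = []
    for site in sites:
        ag = [s for s in samples if sheet.loc[s, "site"] == site and sheet.loc[s, "land_use"] == 1]
        na = [s for s in samples if sheet.loc[s, "site"] == site and sheet.loc[s, "land_use"] == 0]
        for genus in sorted(abundant[site]):
            m_ag = float(relabund.loc[genus, ag].mean())
            m_na = float(relabund.loc[genus, na].mean())
            if m_ag <= 0 or m_na <= 0:
                continue
            ratio, fold, direction = fold_change(m_ag, m_na)
            fold_rows.append(
                {"site": site, "genus": genus, "mean_ag": m_ag, "mean_nonag": m_na,
                 "ratio": ratio, "fold": fold, "direction": direction}
            )
    fold_changes = pd.DataFrame(
        fold_rows,
        columns=["site", "genus", "mean_ag", "mean_nonag", "ratio", "fold", "direction"],
    )

    return {
        "correlations": correlations,
        "abundant_by_site": abundant,
        "venn": venn,
        "signatures": signatures,
        "fold_changes": fold_changes,
    }


def run_study(
    config: sim.SimulationConfig,
    trim_policy: TrimPolicy | None = None,
    thresholds: RankThresholds | None = None,
    analysis: AnalysisConfig | None = None,
) -> tuple[SimulatedDataset, StudyResults]:
    """Simulate one study and run the full analysis on it, in memory."""
    ds = simulate_dataset(config)
    res = analyze(
        ds.db, ds.pairs, ds.barcodes, ds.sheet, ds.soil_df, trim_policy, thresholds, analysis
    )
    return ds, res


# ------------------------------------------------------------- file-based


def _check_outdir(outdir: Path, force: bool) -> None:
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)


def run_simulate(config: sim.SimulationConfig, outdir, *, force: bool = False) -> dict:
    """Write the synthetic dataset to disk; returns the manifest."""
    outdir = Path(outdir)
    _check_outdir(outdir, force)
    ds = simulate_dataset(config)
    write_reference_fasta(ds.db, outdir / "reference.fasta")
    write_fastq_pairs(ds.pairs, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    ds.sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t")
    ds.soil_df.to_csv(outdir / "soil.tsv", sep="\t")
    pd.Series(ds.truth, name="ref_id").rename_axis("read_id").to_csv(
        outdir / "truth.tsv", sep="\t"
    )
    manifest = {"config": asdict(config), "files": {}}
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json":
            manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def run_pipeline(
    reference,
    fwd_fastq,
    rev_fastq,
    sample_sheet_path,
    soil_path,
    outdir,
    *,
    trim_policy: TrimPolicy | None = None,
    thresholds: RankThresholds | None = None,
    analysis: AnalysisConfig | None = None,
    force: bool = False,
) -> StudyResults:
    """File-in, file-out pipeline over the full analysis chain."""
    outdir = Path(outdir)
    _check_outdir(outdir, force)
    db = parse_reference_fasta(reference)
    pairs = read_fastq_pairs(fwd_fastq, rev_fastq)
    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col="sample")
    soil_df = pd.read_csv(soil_path, sep="\t", index_col="sample")
    barcode_map = dict(zip(sheet["barcode"], sheet.index))
    res = analyze(db, pairs, barcode_map, sheet, soil_df, trim_policy, thresholds, analysis)
    write_results(res, outdir)
    return res


def write_results(res: StudyResults, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.demux_report.to_csv(outdir / "demux_report.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "pair_id": a.pair_id,
                "sample": a.sample,
                "status": a.status,
                "lineage": str(a.lineage),
                "effective_identity": round(a.effective_identity, 6),
            }
            for a in res.assignments
        ]
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    for rank, mat in res.counts_by_rank.items():
        mat.to_csv(outdir / f"abundance_{rank}.tsv", sep="\t")
    res.relabund_genus.to_csv(outdir / "relabund_genus.tsv", sep="\t")
    res.soil.to_csv(outdir / "soil_annotated.tsv", sep="\t")
    res.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    res.signatures.to_csv(outdir / "signatures.tsv", sep="\t")
    res.fold_changes.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
    if res.venn is not None:
        regions, shared = res.venn
        venn_df = pd.DataFrame(
            [{"region": k, "count": v} for k, v in regions.items()]
            + [{"region": "shared_fraction", "count": shared}]
        )
        venn_df.to_csv(outdir / "venn.tsv", sep="\t", index=False)


def report(
    relabund: pd.DataFrame,
    signatures: pd.DataFrame,
    venn: tuple[dict[str, int], float] | None,
    sheet: pd.DataFrame,
    top_n: int = 10,
) -> str:
    """Human-readable summary: top genera per site, signatures, Venn."""
    lines: list[str] = []
    samples = list(relabund.columns)
    sites = sorted(sheet["site"].unique())
    for site in sites:
        site_samples = [s for s in samples if sheet.loc[s, "site"] == site]
        ag = [s for s in site_samples if sheet.loc[s, "land_use"] == 1]
        na = [s for s in site_samples if sheet.loc[s, "land_use"] == 0]
        sub = relabund[site_samples]
        order = sub.mean(axis=1).sort_values(ascending=False, kind="stable")
        # alphabetical tie-break on equal means
        order = order.iloc[
            np.lexsort((order.index.to_numpy(), -order.to_numpy()))
        ]
        lines.append(f"== {site}: top {top_n} genera (mean relative abundance, %) ==")
        lines.append(f"{'genus':<20}{'ag_mean':>9}{'ag_sd':>8}{'nonag_mean':>12}{'nonag_sd':>10}")
        for genus in order.index[:top_n]:
            lines.append(
                f"{genus:<20}"
                f"{100 * relabund.loc[genus, ag].mean():>9.3f}"
                f"{100 * relabund.loc[genus, ag].std(ddof=1):>8.3f}"
                f"{100 * relabund.loc[genus, na].mean():>12.3f}"
                f"{100 * relabund.loc[genus, na].std(ddof=1):>10.3f}"
            )
        lines.append("")
    lines.append("== land-use signature genera (|rho| >= 0.5, p <= 0.001 at all sites) ==")
    if signatures.empty:
        lines.append("(none)")
    else:
        for genus, row in signatures.iterrows():
            rhos = ", ".join(f"{s}: {row[s]:+.2f}" for s in sites if s in row)
            lines.append(f"{genus}: {row['direction']} ({rhos})")
    if venn is not None:
        regions, shared = venn
        lines.append("")
        lines.append("== Venn of abundant genera (>= 0.05% site-wide) ==")
        for k, v in regions.items():
            lines.append(f"{k}: {v}")
        lines.append(f"shared fraction (triple / union): {shared:.3f}")
    return "\n".join(lines) + "\n"
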