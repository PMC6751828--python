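"""Test intersection, region annotation and pipeline orchestration.

The scan design is two-pronged: within-population homozygosity (ROH,
consensus regions) and between-population differentiation (windowed Nei
F_ST plus XP-EHH).  Only 500-kb windows flagged by BOTH differentiation
tests become candidate regions, which are then annotated against a
local gene/QTL interval file (BED or GFF3).

``run_pipeline`` executes the whole flow: input (simulated study or
phased VCF) -> per-population inbreeding filter (f_i > 0.05 excluded)
-> per-population QC -> branch A: LD pruning, three-class ROH scan,
long-ROH incidence, >=85% consensus regions -> branch B: F_ST windows
and XP-EHH windows on the unpruned post-QC markers -> intersection ->
annotation.  Every stage writes TSV/BED artifacts plus a MANIFEST and a
plain-text run log; outputs are byte-identical across reruns of the
same config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, fst, roh, xpehh
from .io import (HaplotypePanel, QcThresholds, apply_qc,
                 collapse_to_genotypes, read_phased_vcf)
from .simulate import SimulationConfig, apply_config_key, simulate_study


# ---------------------------------------------------------------------------
# intersection and annotation
# ---------------------------------------------------------------------------

def _check_tiling(df: pd.DataFrame, width_bp: int, what: str) -> None:
    if len(df) == 0:
        return
    start = df["start_bp"].to_numpy()
    end = df["end_bp"].to_numpy()
    if ((start - 1) % width_bp).any() or (end - start + 1 != width_bp).any():
        raise ValueError(f"{what} windows are not on the {width_bp}-bp tiling")


def intersect_tests(fst_windows: pd.DataFrame, xpehh_windows: pd.DataFrame,
                    width_bp: int = fst.WINDOW_BP) -> pd.DataFrame:
    """Windows significant under both differentiation tests.

    ``fst_windows`` must carry a ``significant`` flag column;
    ``xpehh_windows`` holds only retained windows.  Both window sets
    must sit on the same fixed tiling.
    """
    _check_tiling(fst_windows, width_bp, "F_ST")
    _check_tiling(xpehh_windows, width_bp, "XP-EHH")
    sig_fst = fst_windows[fst_windows["significant"]]
    merged = sig_fst.merge(xpehh_windows, on=["chrom", "start_bp", "end_bp"],
                           how="inner", suffixes=("_fst", "_xpehh"))
    cols = ["chrom", "start_bp", "end_bp", "mean_fst", "mean_xpehh",
            "mean_xpehh_all_snps", "n_significant_snps"]
    return merged[cols].sort_values(["chrom", "start_bp"]).reset_index(drop=True)


def read_annotation(path) -> pd.DataFrame:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals
    into 1-based inclusive (chrom, start_bp, end_bp, name) rows."""
    path = Path(path)
    rows = []
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        p = line.rstrip("\n").split("\t")
        try:
            if is_gff:
                if len(p) < 9:
                    raise ValueError("fewer than 9 columns")
                name = next((kv.split("=", 1)[1] for kv in p[8].split(";")
                             if kv.startswith(("ID=", "Name="))), p[2])
                rows.append((p[0], int(p[3]), int(p[4]), name))
            else:
                if len(p) < 3:
                    raise ValueError("fewer than 3 columns")
                start, end = int(p[1]), int(p[2])
                if end <= start:
                    raise ValueError("empty interval")
                name = p[3] if len(p) > 3 else f"feature_{ln}"
                rows.append((p[0], start + 1, end, name))
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: malformed annotation line ({err})")
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def annotate_regions(regions: pd.DataFrame, annotation: pd.DataFrame
                     ) -> pd.DataFrame:
    """Attach the names of features overlapping each region by >= 1 bp.

    Region coordinates are never altered; a feature spanning several
    regions is listed in each.  Gene order within a region follows the
    annotation file.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples():
        # 1-based inclusive -> half-open [start, end+1)
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            row.start_bp, row.end_bp + 1, row.name)
    out = regions.copy()
    genes = []
    for row in out.itertuples():
        tree = trees.get(str(row.chrom))
        hits = tree[row.start_bp:row.end_bp + 1] if tree is not None else ()
        ordered = sorted(hits, key=lambda iv: (iv.begin, iv.data))
        genes.append(",".join(iv.data for iv in ordered))
    out["genes"] = genes
    return out


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything ``run_pipeline`` needs; defaults are the scan's canonical
    values (f_i <= 0.05, 500-kb windows, top 1% F_ST, |XP-EHH| > 4.34,
    >= 3 extreme SNPs per window, 85% consensus)."""

    sim: SimulationConfig | None = None
    vcf_path: str | None = None
    pop_path: str | None = None
    annotation_path: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    prune: diversity.LdPruneParams = field(default_factory=diversity.LdPruneParams)
    consensus_threshold: float = 0.85
    window_bp: int = fst.WINDOW_BP
    fst_top_fraction: float = 0.01
    xpehh_percentile: float = 0.99
    xpehh_threshold: float = xpehh.XPEHH_THRESHOLD
    xpehh_min_snps: int = 3
    ehh_cutoff: float = 0.05
    core_maf_min: float = 0.05

    def __post_init__(self):
        if self.sim is None and (self.vcf_path is None or self.pop_path is None):
            raise ValueError("need either a simulation config or VCF + "
                             "population file paths")


_PIPE_FLOATS = {"consensus_threshold", "fst_top_fraction", "xpehh_percentile",
                "xpehh_threshold", "ehh_cutoff", "core_maf_min"}
_PIPE_INTS = {"window_bp", "xpehh_min_snps"}
_QC_KEYS = {"maf_min", "snp_missing_max", "ind_missing_max", "hwe_p_min",
            "f_i_max"}
_PRUNE_KEYS = {"window_snps": int, "step_snps": int, "r2_max": float}


def read_pipeline_config(path) -> PipelineConfig:
    """Flat ``key = value`` file covering pipeline, QC, pruning and
    simulation keys in one namespace."""
    cfg = PipelineConfig(sim=SimulationConfig())
    sim = cfg.sim
    used_sim = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in _PIPE_FLOATS:
            cfg = replace(cfg, **{key: float(val)})
        elif key in _PIPE_INTS:
            cfg = replace(cfg, **{key: int(val)})
        elif key in ("vcf_path", "pop_path", "annotation_path"):
            cfg = replace(cfg, **{key: val})
        elif key in _QC_KEYS:
            cfg = replace(cfg, qc=replace(cfg.qc, **{key: float(val)}))
        elif key in _PRUNE_KEYS:
            cfg = replace(cfg, prune=replace(cfg.prune,
                                             **{key: _PRUNE_KEYS[key](val)}))
        else:
            try:
                sim = apply_config_key(sim, key, val)
                used_sim = True
            except KeyError:
                raise ValueError(f"{path}:{ln}: unknown key {key!r}") from None
    if cfg.vcf_path is not None and not used_sim:
        cfg = replace(cfg, sim=None)
    else:
        cfg = replace(cfg, sim=sim)
    return cfg


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def _write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    """1-based inclusive start_bp/end_bp -> 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in df.itertuples():
            name = getattr(row, name_col) if name_col else "."
            fh.write(f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\t{name}\n")


def _write_bedgraph(markers, values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, v in zip(markers.chrom, markers.pos, values):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full two-pronged scan; returns a result bundle dict.

    Writes per-stage TSV/BED artifacts under ``outdir`` plus
    ``MANIFEST.tsv`` (stage, artifact, status) and ``run.log``.  On a
    stage failure, partial outputs and the MANIFEST are kept and a
    :class:`StageError` naming the stage is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str, str]] = []
    log: list[str] = []
    results: dict = {}
    stage = "input"

    def emit(name: str, artifact: str):
        manifest.append((stage, artifact, "complete"))

    def finish(status: str):
        mf = pd.DataFrame(manifest, columns=["stage", "artifact", "status"])
        mf.to_csv(outdir / "MANIFEST.tsv", sep="\t", index=False)
        (outdir / "run.log").write_text("\n".join(log) + "\n")

    try:
        # ---- input -------------------------------------------------------
        truth = None
        if config.sim is not None:
            study = simulate_study(config.sim)
            panel, geno, truth = study.panel, study.genotypes, study.truth
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            emit("input", "truth.tsv")
            log.append(f"simulated study: seed={config.sim.seed} "
                       f"pops={config.sim.pop_labels} "
                       f"n={config.sim.n_individuals_per_pop} "
                       f"snps/chrom={config.sim.snps_per_chromosome}")
        else:
            panel = read_phased_vcf(config.vcf_path, config.pop_path)
            geno = collapse_to_genotypes(panel)
            log.append(f"read VCF {config.vcf_path}: {panel.n_individuals} "
                       f"individuals x {panel.n_snps} SNPs")
        pops = list(dict.fromkeys(panel.populations))
        if len(pops) != 2:
            raise ValueError(f"need exactly 2 populations, got {pops}")

        # ---- inbreeding filter ------------------------------------------
        stage = "inbreeding_filter"
        fi_rows = []
        drop: list[str] = []
        for p in pops:
            sub = geno.subset_individuals(geno.individual_indices(p))
            res = diversity.inbreeding_coefficients(sub)
            fi_rows.extend((r.sample_id, p, r.observed_hom, r.expected_hom,
                            r.n_nonmissing, r.f_i) for r in res)
            drop.extend(diversity.flag_inbred(res, config.qc.f_i_max))
        fi_df = pd.DataFrame(fi_rows, columns=["sample_id", "population",
                                               "observed_hom", "expected_hom",
                                               "n_nonmissing", "f_i"])
        fi_df.to_csv(outdir / "inbreeding.tsv", sep="\t", index=False)
        emit(stage, "inbreeding.tsv")
        keep = [i for i, s in enumerate(geno.sample_ids) if s not in set(drop)]
        if not keep:
            raise ValueError("f_i filter removed every individual")
        geno = geno.subset_individuals(np.asarray(keep, dtype=int))
        hap_keep = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in keep]))
        panel = HaplotypePanel(panel.alleles[hap_keep],
                               [panel.sample_ids[i] for i in keep],
                               panel.populations[np.asarray(keep, dtype=int)],
                               panel.markers)
        log.append(f"f_i filter (> {config.qc.f_i_max}): removed {len(drop)} "
                   f"individuals ({sorted(drop)})")

        # ---- QC ----------------------------------------------------------
        stage = "qc"
        geno, qc_report = apply_qc(geno, config.qc)
        qc_report.write_tsv(outdir / "qc_report.tsv")
        emit(stage, "qc_report.tsv")
        log.append(f"QC removals by step: {qc_report.counts()}; "
                   f"{geno.n_individuals} individuals x {geno.n_snps} SNPs remain")
        kept_samples = set(geno.sample_ids)
        keep = [i for i, s in enumerate(panel.sample_ids) if s in kept_samples]
        hap_keep = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in keep]))
        snp_keep = pd.Index(panel.markers.snp_id).get_indexer(geno.markers.snp_id)
        panel = HaplotypePanel(panel.alleles[np.ix_(hap_keep, snp_keep)],
                               [panel.sample_ids[i] for i in keep],
                               panel.populations[np.asarray(keep, dtype=int)],
                               geno.markers)

        # ---- branch A: LD prune -> ROH -> consensus ----------------------
        all_segments: list[roh.ROHSegment] = []
        consensus: dict[str, pd.DataFrame] = {}
        for p in pops:
            stage = f"roh_{p}"
            sub = geno.subset_individuals(geno.individual_indices(p))
            kept = diversity.ld_prune(sub, config.prune)
            pd.Series(sub.markers.snp_id[kept]).to_csv(
                outdir / f"pruned_snps_{p}.txt", index=False, header=False)
            pruned = sub.subset_snps(kept)
            log.append(f"{p}: LD pruning kept {len(kept)}/{sub.n_snps} SNPs")
            segments = roh.scan_all_classes(pruned)
            all_segments.extend(segments)
            seg_df = roh.segments_frame(segments)
            seg_df.to_csv(outdir / f"roh_segments_{p}.tsv", sep="\t", index=False)
            _write_bed(seg_df, outdir / f"roh_segments_{p}.bed", "individual")
            emit(stage, f"roh_segments_{p}.tsv")
            coverage = roh.snp_coverage(segments, pruned, "long")
            _write_bedgraph(pruned.markers, coverage.mean(axis=0),
                            outdir / f"roh_incidence_{p}.bedgraph")
            regions = roh.consensus_regions(coverage, pruned,
                                            config.consensus_threshold)
            cons = roh.consensus_frame(regions)
            cons.to_csv(outdir / f"consensus_{p}.tsv", sep="\t", index=False)
            if len(cons):
                _write_bed(cons, outdir / f"consensus_{p}.bed")
            emit(stage, f"consensus_{p}.tsv")
            consensus[p] = cons
            log.append(f"{p}: {len(seg_df)} ROH segments, "
                       f"{len(cons)} consensus regions "
                       f"(threshold {config.consensus_threshold})")
        summary = roh.roh_summary(
            all_segments, {p: int((geno.populations == p).sum()) for p in pops})
        summary.to_csv(outdir / "roh_summary.tsv", sep="\t", index=False)
        results["roh_summary"] = summary
        results["consensus"] = consensus

        # ---- branch B: F_ST ---------------------------------------------
        stage = "fst"
        fst_snp = fst.per_snp_fst(geno, (pops[0], pops[1]))
        pd.DataFrame({"snp_id": geno.markers.snp_id, "chrom": geno.markers.chrom,
                      "pos": geno.markers.pos, "fst": fst_snp}
                     ).to_csv(outdir / "fst_snp.tsv", sep="\t", index=False)
        windows = fst.window_average(fst_snp, geno, config.window_bp)
        cutoff, flagged = fst.empirical_cutoff(windows, config.fst_top_fraction)
        flagged = flagged.rename(columns={"mean": "mean_fst"})
        flagged.to_csv(outdir / "fst_windows.tsv", sep="\t", index=False)
        _write_bed(flagged[flagged["significant"]], outdir / "fst_significant.bed")
        emit(stage, "fst_windows.tsv")
        log.append(f"F_ST: {len(flagged)} windows, cutoff {cutoff:.6g}, "
                   f"{int(flagged['significant'].sum())} significant")
        results["fst_windows"] = flagged
        results["fst_cutoff"] = cutoff

        # ---- branch B: XP-EHH -------------------------------------------
        stage = "xpehh"
        records = xpehh.xpehh(panel, pops[0], pops[1],
                              ehh_cutoff=config.ehh_cutoff,
                              maf_min=config.core_maf_min)
        records.to_csv(outdir / "xpehh_snp.tsv", sep="\t", index=False)
        xp_windows = xpehh.significant_windows(
            records, config.window_bp, config.xpehh_min_snps,
            config.xpehh_percentile, config.xpehh_threshold)
        xp_windows.to_csv(outdir / "xpehh_windows.tsv", sep="\t", index=False)
        emit(stage, "xpehh_windows.tsv")
        n_fdr = int((records["q_value"] < 0.05).sum())
        log.append(f"XP-EHH: {len(records)} cores, "
                   f"{int((records['standardized'].abs() > config.xpehh_threshold).sum())} "
                   f"beyond +-{config.xpehh_threshold}, {n_fdr} FDR-significant, "
                   f"{len(xp_windows)} candidate windows")
        results["xpehh_records"] = records
        results["xpehh_windows"] = xp_windows

        # ---- intersection + annotation ----------------------------------
        stage = "intersect"
        candidates = intersect_tests(flagged, xp_windows, config.window_bp)
        if config.annotation_path:
            candidates = annotate_regions(candidates,
                                          read_annotation(config.annotation_path))
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        if len(candidates):
            _write_bed(candidates, outdir / "candidates.bed")
        emit(stage, "candidates.tsv")
        log.append(f"intersection: {len(candidates)} candidate regions")
        results["candidates"] = candidates

        # ---- truth recovery (simulation runs only) -----------------------
        if truth is not None and len(truth):
            stage = "truth_recovery"
            for t in truth.itertuples():
                if t.kind == "sweep":
                    hit = ((candidates["chrom"] == t.chrom)
                           & (candidates["start_bp"] <= t.end_bp)
                           & (candidates["end_bp"] >= t.start_bp)).any()
                    what = f"sweep:{t.chrom}:{t.start_bp}-{t.end_bp}"
                else:
                    cons = consensus.get(t.population, pd.DataFrame())
                    hit = (len(cons) > 0 and
                           ((cons["chrom"] == t.chrom)
                            & (cons["start_bp"] <= t.end_bp)
                            & (cons["end_bp"] >= t.start_bp)).any())
                    what = f"roh:{t.chrom}:{t.start_bp}-{t.end_bp}"
                manifest.append((stage, what,
                                 "recovered" if hit else "not_recovered"))
    except Exception as err:
        manifest.append((stage, "-", "failed"))
        finish("failed")
        raise StageError(stage, err) from err

    finish("complete")
    return results
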