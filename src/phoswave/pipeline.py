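"""End-to-end orchestration of the three analysis designs.

``run_timecourse`` executes the block-release timecourse analysis on
in-memory matrices: flag removal, channel-median scaling, phospho-to-
protein normalization, replicate (batch) correction, detection filtering,
differential calling versus time zero and between strains, replicate
averaging and mean scaling, temporal clustering, kinase-motif enrichment,
residue logos and sub-motif discovery, and optional over-representation
analysis.  ``run_arrest`` and ``run_inhibition`` cover the replicate-only
designs.  :func:`run` wraps these with file I/O, a declarative YAML
config, logging and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, cluster, dynamics, filter_qc, go_enrich, mq_io
from . import motifs as motifs_mod
from .dynamics import AnalysisConfig
from .filter_qc import FilterConfig
from .mq_io import SampleDesign

log = logging.getLogger(__name__)


@dataclass
class TimecourseResult:
    """All artefacts of a timecourse run, keyed by stage."""

    protein_matrix: pd.DataFrame          # normalized, batch-corrected
    site_matrix: pd.DataFrame             # protein-normalized site ratios
    protein_filter_audit: filter_qc.FilterAudit
    site_filter_audit: filter_qc.FilterAudit
    protein_calls: pd.DataFrame           # vs-t0, long format
    site_calls: pd.DataFrame
    strain_site_calls: pd.DataFrame | None
    protein_summary: pd.DataFrame
    site_summary: pd.DataFrame
    strain_site_summary: pd.DataFrame | None
    averaged_scaled: pd.DataFrame         # mean-scaled averaged profiles
    clusters: cluster.ClusterResult | None
    cluster_profiles: pd.DataFrame | None
    motif_matches: pd.DataFrame
    motif_enrichment: pd.DataFrame | None
    logo: pd.DataFrame | None
    submotif: pd.DataFrame | None
    normalization_reports: dict[str, pd.DataFrame]
    stage_counts: dict[str, int]


def _pe_to_n_channel_map(design: SampleDesign) -> dict[str, str]:
    n_table = design.subset("N").set_index(
        ["strain", "replicate", "timepoint_min"])["channel_label"]
    mapping = {}
    for _, row in design.subset("PE").iterrows():
        key = (row["strain"], row["replicate"], row["timepoint_min"])
        mapping[row["channel_label"]] = n_table.loc[key]
    return mapping


def _site_normalizable(
    protein_matrix: pd.DataFrame,
    site_protein: pd.Series,
    design: SampleDesign,
    strains: Sequence[str],
) -> pd.Series:
    """True when the parent protein is nonzero in every N channel of every
    required strain (the strictest reading of normalizable-at-all-
    timepoints: either replicate's zero excludes the site)."""
    chans: list[str] = []
    for strain in strains:
        chans.extend(design.channels(enrichment="N", strain=strain))
    nonzero_all = (protein_matrix[chans] > 0).all(axis=1)
    ok = site_protein.map(nonzero_all).fillna(False).astype(bool)
    return ok


def run_timecourse(
    design: SampleDesign,
    protein_matrix: pd.DataFrame,
    protein_meta: pd.DataFrame,
    phospho_matrix: pd.DataFrame,
    phospho_meta: pd.DataFrame,
    filter_config: FilterConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    strains: Sequence[str] | None = None,
    cluster_k: int | None = None,
    cluster_kmax: int = 15,
    cluster_features: str = "dynamic",   # or "all"
    motif_patterns: Sequence[motifs_mod.MotifPattern] | None = None,
    submotif_base: str = "[DEN]x[ST]*",
    submotif_offset: int = 1,
    term_map: go_enrich.TermMap | None = None,
) -> TimecourseResult:
    """The complete timecourse analysis on in-memory matrices."""
    filter_config = filter_config or FilterConfig()
    analysis_config = analysis_config or AnalysisConfig(
        timepoints=design.timepoints)
    strains = tuple(strains) if strains else design.strains
    motif_patterns = (list(motif_patterns) if motif_patterns is not None
                      else motifs_mod.builtin_kinase_motifs())
    counts: dict[str, int] = {
        "proteins_input": len(protein_matrix),
        "sites_input": len(phospho_matrix),
    }

    # 1. search-engine flags
    keep_p, pflags = filter_qc.drop_flagged_features(protein_meta)
    keep_s, sflags = filter_qc.drop_flagged_features(phospho_meta)
    protein_matrix = protein_matrix.loc[keep_p]
    protein_meta = protein_meta.loc[keep_p]
    phospho_matrix = phospho_matrix.loc[keep_s]
    phospho_meta = phospho_meta.loc[keep_s]
    counts["proteins_flag_removed"] = pflags["removed"]
    counts["sites_flag_removed"] = sflags["removed"]

    # 2. channel-median scaling, separately per enrichment type
    n_scaled, n_report = normalize_channels(protein_matrix)
    pe_scaled, pe_report = normalize_channels(phospho_matrix)

    # 3. phospho-to-protein ratios (x1000) on matched channels
    site_protein = phospho_meta["protein_id"]
    known = site_protein.isin(n_scaled.index)
    if not known.all():
        log.info("dropping %d sites whose protein is absent from the "
                 "protein table", int((~known).sum()))
        pe_scaled = pe_scaled.loc[known]
        phospho_meta = phospho_meta.loc[known]
        site_protein = site_protein.loc[known]
    ratio = normalize_phospho(pe_scaled, n_scaled, site_protein, design)

    # 4. replicate (batch) correction on the log2 scale
    n_batches = [
        int(design.subset("N").set_index("channel_label")
            .loc[c, "replicate"]) for c in n_scaled.columns
    ]
    pe_batches = [
        int(design.subset("PE").set_index("channel_label")
            .loc[c, "replicate"]) for c in ratio.columns
    ]
    from .normalize import correct_batch
    n_corrected = correct_batch(n_scaled, n_batches)
    ratio_corrected = correct_batch(ratio.fillna(0.0), pe_batches)

    # 5. detection filters
    keep_p, p_audit = filter_qc.detection_filter(
        n_corrected, design, filter_config, kind="protein", strains=strains)
    normalizable = _site_normalizable(
        n_corrected, site_protein, design, strains)
    keep_s, s_audit = filter_qc.detection_filter(
        ratio_corrected, design, filter_config, kind="phospho",
        strains=strains,
        localization=phospho_meta["localization_prob"],
        normalizable=normalizable,
    )
    proteins = n_corrected.loc[keep_p]
    sites = ratio_corrected.loc[keep_s]
    site_meta = phospho_meta.loc[keep_s]
    counts["proteins_final"] = len(proteins)
    counts["sites_final"] = len(sites)

    # 6. differential calling
    prot_min = dynamics.dataset_minimum(proteins)
    site_min = dynamics.dataset_minimum(sites)
    prot_comps, site_comps = [], []
    for strain in strains:
        prot_comps += dynamics.timecourse_comparisons(design, strain, "N")
        site_comps += dynamics.timecourse_comparisons(design, strain, "PE")
    protein_calls = dynamics.call_differential(
        proteins, prot_comps, analysis_config, prot_min)
    site_calls = dynamics.call_differential(
        sites, site_comps, analysis_config, site_min)
    protein_summary = dynamics.summarize_calls(protein_calls)
    site_summary = dynamics.summarize_calls(site_calls)
    counts["proteins_dynamic"] = int(protein_summary["dynamic"].sum())
    counts["sites_dynamic"] = int(site_summary["dynamic"].sum())

    strain_site_calls = strain_site_summary = None
    if len(strains) >= 2:
        comps = dynamics.strain_comparisons(design, strains[0], strains[1],
                                            "PE")
        strain_site_calls = dynamics.call_differential(
            sites, comps, analysis_config, site_min)
        strain_site_summary = dynamics.summarize_calls(strain_site_calls)
        counts["sites_strain_different"] = int(
            strain_site_summary["dynamic"].sum())

    # 7. replicate averaging and mean scaling (combined scope)
    blocks = []
    for strain in strains:
        avg = dynamics.average_replicate_channels(sites, design, strain, "PE")
        avg.columns = [f"{strain}:t{tp}" for tp in avg.columns]
        blocks.append(avg)
    averaged = pd.concat(blocks, axis=1)
    averaged_scaled, excluded = dynamics.scale_profiles(averaged, mode="mean")
    counts["sites_zero_mean_excluded"] = len(excluded)

    # 8. clustering of dynamic features
    clusters = cluster_profiles = None
    if cluster_features == "all":
        to_cluster = averaged_scaled.index
    else:
        dyn = site_summary.index[site_summary["dynamic"]]
        to_cluster = averaged_scaled.index.intersection(dyn)
    if len(to_cluster) >= 2:
        cluster_profiles = averaged_scaled.loc[to_cluster]
        clusters = cluster.ward_cluster(cluster_profiles, k=cluster_k,
                                        kmax=cluster_kmax)
        counts["clusters_k"] = clusters.k

    # 9. motif matching and enrichment (cluster vs total)
    windows = site_meta["window"]
    matches = motifs_mod.match_table(windows, motif_patterns)
    enrichment = None
    if clusters is not None:
        groups = {
            f"cluster_{cid}": list(clusters.members(cid))
            for cid in range(1, clusters.k + 1)
        }
        enrichment = motifs_mod.motif_enrichment(
            groups, background=list(clusters.labels.index), matches=matches)

    # 10. strain-difference logo and sub-motif discovery
    logo = submotif = None
    if strain_site_summary is not None:
        # strain contrasts are ref = first strain (wild type), test = second
        # (mutant), so "decreased" means reduced in the mutant
        decreased = strain_site_summary.index[
            strain_site_summary["direction"] == "decreased"]
        unchanged = strain_site_summary.index[
            strain_site_summary["direction"] == "no_change"]
        if len(decreased) and len(unchanged):
            fg = [windows.loc[s] for s in decreased]
            bg = [windows.loc[s] for s in unchanged]
            logo = motifs_mod.residue_logo(fg, bg,
                                           alpha=analysis_config.alpha)
            base = motifs_mod.parse_motif(submotif_base)
            if (any(motifs_mod.match_site(w, base) for w in fg)
                    and any(motifs_mod.match_site(w, base) for w in bg)):
                submotif = motifs_mod.discover_submotif(
                    base, submotif_offset, fg, bg,
                    alpha=analysis_config.alpha)

    # 11. over-representation analysis of decreased-site proteins
    ora_result = None
    if term_map is not None and strain_site_summary is not None:
        fg_proteins = set(
            site_meta.loc[
                strain_site_summary.index[
                    strain_site_summary["direction"] == "decreased"],
                "protein_id",
            ]
        )
        if fg_proteins:
            ora_result = go_enrich.ora(fg_proteins, term_map,
                                       alpha=analysis_config.alpha)

    result = TimecourseResult(
        protein_matrix=proteins,
        site_matrix=sites,
        protein_filter_audit=p_audit,
        site_filter_audit=s_audit,
        protein_calls=protein_calls,
        site_calls=site_calls,
        strain_site_calls=strain_site_calls,
        protein_summary=protein_summary,
        site_summary=site_summary,
        strain_site_summary=strain_site_summary,
        averaged_scaled=averaged_scaled,
        clusters=clusters,
        cluster_profiles=cluster_profiles,
        motif_matches=matches,
        motif_enrichment=enrichment,
        logo=logo,
        submotif=submotif,
        normalization_reports={
            "N": n_report.to_frame(), "PE": pe_report.to_frame()},
        stage_counts=counts,
    )
    result.ora = ora_result  # type: ignore[attr-defined]
    return result


def normalize_channels(matrix):
    from .normalize import median_scale_channels
    return median_scale_channels(matrix)


def normalize_phospho(pe, n, site_protein, design):
    from .normalize import phospho_to_protein
    return phospho_to_protein(
        pe, n, dict(site_protein), _pe_to_n_channel_map(design))


# ---------------------------------------------------------------------------
# Replicate-only designs
# ---------------------------------------------------------------------------


def run_arrest(
    design: SampleDesign,
    protein_matrix: pd.DataFrame,
    protein_meta: pd.DataFrame,
    phospho_matrix: pd.DataFrame,
    phospho_meta: pd.DataFrame,
    min_reps: int = 3,
    strains: Sequence[str] | None = None,
    analysis_config: AnalysisConfig | None = None,
    min_localization: float = 0.75,
) -> dict[str, pd.DataFrame]:
    """Metaphase-arrest style analysis: replicate detection rule, then
    strain-vs-strain calls over all replicates of each strain pair."""
    analysis_config = analysis_config or AnalysisConfig()
    strains = tuple(strains) if strains else design.strains
    keep_p, _ = filter_qc.drop_flagged_features(protein_meta)
    keep_s, _ = filter_qc.drop_flagged_features(phospho_meta)
    n_scaled, _ = normalize_channels(protein_matrix.loc[keep_p])
    pe_scaled, _ = normalize_channels(phospho_matrix.loc[keep_s])
    phospho_meta = phospho_meta.loc[keep_s]
    keep = filter_qc.arrest_detection_filter(
        n_scaled, design, min_reps, strains, enrichment="N")
    proteins = n_scaled.loc[keep]
    loc_ok = phospho_meta["localization_prob"] > min_localization
    keep = filter_qc.arrest_detection_filter(
        pe_scaled.loc[loc_ok], design, min_reps, strains, enrichment="PE")
    sites = pe_scaled.loc[keep]
    out = {"proteins": proteins, "sites": sites}
    ref = strains[0]
    for other in strains[1:]:
        for label, matrix, dmin in (
            ("proteins", proteins, dynamics.dataset_minimum(proteins)),
            ("sites", sites, dynamics.dataset_minimum(sites)),
        ):
            comp = dynamics.arrest_comparison(design, ref, other,
                                              "N" if label == "proteins"
                                              else "PE")
            out[f"{label}_{ref}_vs_{other}"] = dynamics.call_differential(
                matrix, [comp], analysis_config, dmin)
    return out


def run_inhibition(
    design: SampleDesign,
    phospho_matrix: pd.DataFrame,
    phospho_meta: pd.DataFrame,
    min_reps: int,
    strains: Sequence[str] | None = None,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Analogue-sensitive inhibition analysis: categorize sites by median
    fold change alone (inhibited strain / wild type) after a replicate
    detection rule; non-finite fold changes become ``no_change``."""
    strains = tuple(strains) if strains else design.strains
    if len(strains) != 2:
        raise ValueError("inhibition design needs exactly two strains")
    keep_s, _ = filter_qc.drop_flagged_features(phospho_meta)
    pe_scaled, _ = normalize_channels(phospho_matrix.loc[keep_s])
    keep = filter_qc.arrest_detection_filter(
        pe_scaled, design, min_reps, strains, enrichment="PE")
    sites = pe_scaled.loc[keep]
    ref_ch = design.channels(enrichment="PE", strain=strains[0])
    test_ch = design.channels(enrichment="PE", strain=strains[1])
    A = sites[ref_ch].to_numpy(dtype=float)
    B = sites[test_ch].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if A.shape[1] == B.shape[1]:
            fc = np.median(B / A, axis=1)
        else:
            fc = np.median(B, axis=1) / np.median(A, axis=1)
    category = np.where(
        ~np.isfinite(fc), "no_change",
        np.where(fc > fc_threshold, "increased",
                 np.where(fc < 1.0 / fc_threshold, "decreased", "no_change")),
    )
    return pd.DataFrame({
        "feature": sites.index,
        "median_fc": fc,
        "category": category,
    })


# ---------------------------------------------------------------------------
# Declarative runner
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative description of one analysis run (YAML-backed)."""

    design_kind: str                    # timecourse | arrest | inhibition
    design_path: str
    protein_path: str
    phospho_path: str
    output_dir: str
    seed: int = 0
    strains: tuple[str, ...] | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    cluster_k: int | None = None
    cluster_kmax: int = 15
    motif_table: str | None = None
    term_map: str | None = None
    min_reps: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kind = raw.get("design_kind")
        if kind not in ("timecourse", "arrest", "inhibition"):
            raise ValueError(f"unknown design kind {kind!r}")
        filt = FilterConfig(**raw.get("filter", {}))
        ana_kwargs = dict(raw.get("analysis", {}))
        if "timepoints" in ana_kwargs:
            ana_kwargs["timepoints"] = tuple(ana_kwargs["timepoints"])
        ana = AnalysisConfig(**ana_kwargs)
        return cls(
            design_kind=kind,
            design_path=raw["design_path"],
            protein_path=raw["protein_path"],
            phospho_path=raw["phospho_path"],
            output_dir=raw.get("output_dir", "phoswave_out"),
            seed=int(raw.get("seed", 0)),
            strains=tuple(raw["strains"]) if raw.get("strains") else None,
            filter=filt,
            analysis=ana,
            cluster_k=raw.get("cluster_k"),
            cluster_kmax=int(raw.get("cluster_kmax", 15)),
            motif_table=raw.get("motif_table"),
            term_map=raw.get("term_map"),
            min_reps=int(raw.get("min_reps", 3)),
        )

    def validate_against(self, design: SampleDesign) -> None:
        if self.design_kind == "timecourse":
            if len(design.timepoints) < 2:
                raise ValueError(
                    "timecourse design requires multiple timepoints in the "
                    "sample design")
            for tp in (self.analysis.metaphase_I, self.analysis.metaphase_II):
                if tp not in design.timepoints:
                    raise ValueError(
                        f"analysis anchor {tp} min not in the sample design")
        else:
            if len(design.timepoints) > 1:
                raise ValueError(
                    f"{self.design_kind} design expects a replicate-only "
                    "sample design, but multiple timepoints are present")


def run(config: RunConfig) -> dict:
    """Execute a configured run; returns (and writes) the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "design_kind": config.design_kind,
        "stages": {},
    }
    try:
        design = SampleDesign.from_tsv(config.design_path)
        config.validate_against(design)
        protein_records = mq_io.read_protein_table(config.protein_path,
                                                   design)
        phospho_records = mq_io.read_phospho_table(config.phospho_path,
                                                   design)
        pm, pmeta = mq_io.protein_frame(protein_records, design)
        sm, smeta = mq_io.phospho_frame(phospho_records, design)
        manifest["stages"]["read"] = {
            "proteins": len(pm), "sites": len(sm)}
        patterns = (mq_io.read_motif_table(config.motif_table)
                    if config.motif_table else None)
        tmap = (go_enrich.TermMap.from_tsv(config.term_map)
                if config.term_map else None)
        if config.design_kind == "timecourse":
            res = run_timecourse(
                design, pm, pmeta, sm, smeta,
                filter_config=config.filter,
                analysis_config=config.analysis,
                strains=config.strains,
                cluster_k=config.cluster_k,
                cluster_kmax=config.cluster_kmax,
                motif_patterns=patterns,
                term_map=tmap,
            )
            write_timecourse_outputs(res, outdir)
            manifest["stages"].update(res.stage_counts)
        elif config.design_kind == "arrest":
            tables = run_arrest(design, pm, pmeta, sm, smeta,
                                min_reps=config.min_reps,
                                strains=config.strains,
                                analysis_config=config.analysis)
            for name, df in tables.items():
                mq_io.write_table(df, outdir / f"arrest_{name}.tsv")
                manifest["stages"][name] = len(df)
        else:
            calls = run_inhibition(design, sm, smeta,
                                   min_reps=config.min_reps,
                                   strains=config.strains,
                                   fc_threshold=config.analysis.fc_threshold)
            mq_io.write_table(calls, outdir / "inhibition_calls.tsv",
                              index=False)
            manifest["stages"]["sites"] = len(calls)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["stages"], sort_keys=True).encode()
        + str(config).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest


def write_timecourse_outputs(res: TimecourseResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mq_io.write_table(res.protein_matrix, outdir / "proteins_normalized.tsv")
    mq_io.write_table(res.site_matrix, outdir / "sites_normalized.tsv")
    mq_io.write_table(res.protein_calls, outdir / "protein_calls.tsv",
                      index=False)
    mq_io.write_table(res.site_calls, outdir / "site_calls.tsv", index=False)
    mq_io.write_table(res.protein_summary, outdir / "protein_summary.tsv")
    mq_io.write_table(res.site_summary, outdir / "site_summary.tsv")
    if res.strain_site_calls is not None:
        mq_io.write_table(res.strain_site_calls,
                          outdir / "strain_site_calls.tsv", index=False)
        mq_io.write_table(res.strain_site_summary,
                          outdir / "strain_site_summary.tsv")
    mq_io.write_table(res.averaged_scaled, outdir / "profiles_scaled.tsv")
    for name, rep in res.normalization_reports.items():
        mq_io.write_table(rep, outdir / f"normalization_{name}.tsv",
                          index=False)
    mq_io.write_table(res.protein_filter_audit.to_frame(),
                      outdir / "protein_filter_audit.tsv", index=False)
    mq_io.write_table(res.site_filter_audit.to_frame(),
                      outdir / "site_filter_audit.tsv", index=False)
    if res.clusters is not None:
        mq_io.write_table(res.clusters.labels.to_frame(),
                          outdir / "cluster_assignments.tsv")
        mq_io.write_table(cluster.linkage_frame(res.clusters),
                          outdir / "cluster_linkage.tsv", index=False)
        mq_io.write_table(res.clusters.wss_curve.to_frame(),
                          outdir / "cluster_wss.tsv")
        mq_io.write_table(
            cluster.cluster_summary(res.cluster_profiles, res.clusters),
            outdir / "cluster_summary.tsv", index=False)
    mq_io.write_table(res.motif_matches, outdir / "motif_matches.tsv")
    if res.motif_enrichment is not None:
        mq_io.write_table(res.motif_enrichment,
                          outdir / "motif_enrichment.tsv", index=False)
    if res.logo is not None:
        mq_io.write_table(res.logo, outdir / "logo_matrix.tsv", index=False)
    if res.submotif is not None:
        mq_io.write_table(res.submotif, outdir / "submotif.tsv", index=False)
    ora = getattr(res, "ora", None)
    if ora is not None:
        mq_io.write_table(ora, outdir / "ora.tsv", index=False)
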