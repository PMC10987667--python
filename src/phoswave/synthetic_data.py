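"""Synthetic multiplexed proteome/phosphoproteome time courses with truth.

The generator emulates the statistical structure of a two-strain,
two-replicate, ten-timepoint TMT block-release experiment: protein
abundance profiles, singly-phosphorylated sites with +/-15-residue
windows, kinase-activity waves multiplying the phospho signal of
motif-carrying sites, per-channel scaling, per-feature replicate (batch)
offsets, multiplicative log-normal noise, intensity-dependent dropout
recorded as zeros, localization probabilities, and decoy/contaminant rows.

Default kinase classes:

* a biphasic Cdk-type wave ([ST]*Px[KR]) peaking at both meiotic
  divisions, identical in the two strains;
* a Polo-type meiosis-I wave ([DEN]x[ST]*F) peaking at 75 min in the
  wild type and abolished in the mutant — the only planted source of
  strain differences;
* a late casein-kinase-type wave ([ST]xx[ST]*) rising through meiosis II,
  identical in the two strains.

Protein sequences are generated first and motif residues are written into
them, so sequence windows, site positions and the emitted FASTA agree.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import mq_io
from .dynamics import DEFAULT_TIMEPOINTS
from .motifs import AMINO_ACIDS, MotifPattern, SiteWindow, parse_motif

STRAINS = ("wild_type", "mutant")
STRAIN_SHORT = {"wild_type": "wt", "mutant": "mut"}


@dataclass(frozen=True)
class KinaseSpec:
    """A planted kinase: its consensus motif, per-strain activity wave and
    the fraction of sites assigned to it."""

    pattern_text: str
    activity: Mapping[str, tuple[float, ...]]
    fraction: float

    def pattern(self, name: str) -> MotifPattern:
        return parse_motif(self.pattern_text, name)


def _default_kinases() -> dict[str, KinaseSpec]:
    biphasic = (1.0, 1.6, 2.4, 3.0, 1.8, 1.4, 3.0, 2.2, 1.4, 1.1)
    mei1 = (1.0, 1.6, 2.4, 3.0, 2.4, 1.6, 1.0, 1.0, 1.0, 1.0)
    late = (1.0, 1.0, 1.0, 1.0, 1.2, 1.5, 2.0, 2.5, 3.0, 3.0)
    flat = tuple([1.0] * 10)
    return {
        "cdk_biphasic": KinaseSpec(
            "[ST]*Px[KR]",
            {"wild_type": biphasic, "mutant": biphasic},
            fraction=0.10,
        ),
        "polo_meiosisI": KinaseSpec(
            "[DEN]x[ST]*F",
            {"wild_type": mei1, "mutant": flat},
            fraction=0.10,
        ),
        "ck1_late": KinaseSpec(
            "[ST]xx[ST]*",
            {"wild_type": late, "mutant": late},
            fraction=0.10,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated experiment.

    noise_cv is the coefficient of variation of the mean-one log-normal
    measurement noise applied independently to every reporter value of
    both tables.  Dropout is intensity-dependent:
    P(zero | I) = 1 / (1 + exp(slope * (log10 I - midpoint))), calibrated
    so that roughly 10% of phospho-site reporter values are zero under the
    defaults; protein-table values are brighter (aggregates of many
    peptides) and drop out rarely under the same model.
    """

    n_proteins: int = 1000
    n_sites: int = 2000
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 2
    strains: tuple[str, ...] = STRAINS
    kinases: Mapping[str, KinaseSpec] = field(default_factory=_default_kinases)
    baseline_log10_mean: float = 6.0
    baseline_log10_sd: float = 0.5
    protein_boost_log10: float = 1.3   # protein table brightness over sites
    site_level_log10_sd: float = 0.4   # site stoichiometry spread
    noise_cv: float = 0.2
    channel_scale_sd_log2: float = 0.25
    batch_effect_sd_log2: float = 0.3
    dropout_midpoint_log10: float = 4.35
    dropout_slope: float = 2.5
    loc_pass_fraction: float = 0.85
    acceptor_probs: tuple[float, float, float] = (0.85, 0.149, 0.001)  # S,T,Y
    fraction_reverse: float = 0.02
    fraction_contaminant: float = 0.02
    fraction_dynamic_proteins: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(k.fraction for k in self.kinases.values())
        if total >= 1.0:
            raise ValueError("kinase fractions must sum to below 1")
        for name, spec in self.kinases.items():
            for strain in self.strains:
                prof = spec.activity[strain]
                if len(prof) != len(self.timepoints):
                    raise ValueError(
                        f"kinase {name}: activity length != timepoints")
                if min(prof) <= 0:
                    raise ValueError(f"kinase {name}: activity must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth covering every emitted non-decoy feature."""

    sites: pd.DataFrame      # kinase, class_id, true_dynamic, true_strain_diff
    proteins: pd.DataFrame   # profile_class, true_dynamic
    activities: dict[tuple[str, str], np.ndarray]  # (kinase, strain) -> wave
    summary: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.sites.to_csv(outdir / "truth_sites.tsv", sep="\t")
        self.proteins.to_csv(outdir / "truth_proteins.tsv", sep="\t")
        rows = [
            {"kinase": k, "strain": s,
             **{f"t{tp}": v for tp, v in zip(DEFAULT_TIMEPOINTS, wave)}}
            for (k, s), wave in self.activities.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth_activities.tsv",
                                  sep="\t", index=False)


@dataclass
class SyntheticDataset:
    design: mq_io.SampleDesign
    protein_matrix: pd.DataFrame
    protein_meta: pd.DataFrame
    phospho_matrix: pd.DataFrame
    phospho_meta: pd.DataFrame
    truth: SyntheticTruth
    fasta: dict[str, str]
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the MaxQuant-dialect TSVs, design, FASTA and truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteinGroups.tsv",
            "phospho": outdir / "phospho_sites.tsv",
            "design": outdir / "sample_design.tsv",
            "fasta": outdir / "proteins.fasta",
        }
        mq_io.write_protein_table(self.protein_matrix, self.protein_meta,
                                  paths["proteins"])
        mq_io.write_phospho_table(self.phospho_matrix, self.phospho_meta,
                                  paths["phospho"])
        self.design.to_tsv(paths["design"])
        with open(paths["fasta"], "w") as fh:
            for pid, seq in self.fasta.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        self.truth.write(outdir)
        return paths


def _make_design(config: SimConfig) -> mq_io.SampleDesign:
    rows = []
    for enr in ("N", "PE"):
        for strain in config.strains:
            for rep in range(1, config.n_replicates + 1):
                for tp in config.timepoints:
                    rows.append({
                        "channel_label":
                            f"{STRAIN_SHORT.get(strain, strain)}{rep}"
                            f"_t{tp:03d}_{enr}",
                        "strain": strain,
                        "replicate": rep,
                        "timepoint_min": tp,
                        "enrichment": enr,
                    })
    return mq_io.SampleDesign(pd.DataFrame(rows))


def _protein_profiles(config: SimConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(n_proteins x n_tp profile matrix, class codes 0=flat 1=up 2=down)."""
    n_tp = len(config.timepoints)
    classes = np.zeros(config.n_proteins, dtype=int)
    n_dyn = int(round(config.fraction_dynamic_proteins * config.n_proteins))
    dyn_idx = rng.choice(config.n_proteins, size=n_dyn, replace=False)
    classes[dyn_idx[: n_dyn // 2]] = 1
    classes[dyn_idx[n_dyn // 2 :]] = 2
    t = np.linspace(0.0, 1.0, n_tp)
    up = 1.0 + 1.5 * t          # induction across the course
    down = 1.0 - 0.6 * t        # progressive loss
    profiles = np.ones((config.n_proteins, n_tp))
    profiles[classes == 1] = up
    profiles[classes == 2] = down
    return profiles, classes


def _draw_localization(config: SimConfig, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Bimodal localization probabilities: a confident mode above 0.75 and
    an ambiguous mode below it."""
    passes = rng.random(n) < config.loc_pass_fraction
    hi = 0.75 + 0.25 * rng.beta(2.0, 1.0, size=n)
    lo = 0.40 + 0.35 * rng.random(n)
    return np.round(np.where(passes, hi, lo), 6)


def _lognormal_noise(cv: float, size: tuple[int, ...],
                     rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=size))


def dropout_probability(intensity: np.ndarray, config: SimConfig) -> np.ndarray:
    """P(recorded as zero) as a function of the underlying intensity."""
    with np.errstate(divide="ignore"):
        x = np.log10(np.maximum(intensity, 1e-12))
    z = np.clip(config.dropout_slope * (x - config.dropout_midpoint_log10),
                -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def generate_dataset(config: SimConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Simulate the full two-strain timecourse with known ground truth."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    n_tp = len(config.timepoints)
    design = _make_design(config)

    # --- proteins -----------------------------------------------------------
    protein_ids = [f"YSY{i:04d}" for i in range(config.n_proteins)]
    lengths = rng.integers(200, 1200, size=config.n_proteins)
    sequences = [
        np.frombuffer(
            bytes(rng.choice(np.frombuffer(AMINO_ACIDS.encode(), np.uint8),
                             size=L)), np.uint8
        ).copy()
        for L in lengths
    ]
    baseline = 10.0 ** rng.normal(config.baseline_log10_mean,
                                  config.baseline_log10_sd,
                                  config.n_proteins)
    profiles, prot_classes = _protein_profiles(config, rng)

    # --- site placement and motif planting ----------------------------------
    kinase_names = list(config.kinases)
    class_sizes = [int(round(config.kinases[k].fraction * config.n_sites))
                   for k in kinase_names]
    site_kinase = np.array(
        sum(([k] * s for k, s in zip(kinase_names, class_sizes)), [])
        + [""] * (config.n_sites - sum(class_sizes)),
        dtype=object,
    )
    rng.shuffle(site_kinase)
    patterns = {k: config.kinases[k].pattern(k) for k in kinase_names}
    acceptor_alphabet = np.array(list("STY"))

    site_protein_idx = np.empty(config.n_sites, dtype=int)
    site_position = np.empty(config.n_sites, dtype=int)  # 1-based
    used_positions: dict[int, list[int]] = {}
    for s in range(config.n_sites):
        while True:
            p = int(rng.integers(0, config.n_proteins))
            L = int(lengths[p])
            pos = int(rng.integers(5, L - 4))  # 0-based, keep +/-4 inside
            if all(abs(pos - q) >= 8 for q in used_positions.get(p, ())):
                break
        used_positions.setdefault(p, []).append(pos)
        site_protein_idx[s] = p
        site_position[s] = pos + 1

    for s in range(config.n_sites):
        seq = sequences[site_protein_idx[s]]
        center = site_position[s] - 1
        kin = site_kinase[s]
        if kin:
            for off, residues in patterns[kin].constraints.items():
                choice = rng.choice(sorted(residues))
                seq[center + off] = ord(choice)
        else:
            acceptor = rng.choice(acceptor_alphabet,
                                  p=np.asarray(config.acceptor_probs))
            seq[center] = ord(str(acceptor))

    fasta = {pid: seq.tobytes().decode() for pid, seq in
             zip(protein_ids, sequences)}

    half = 15
    windows = []
    for s in range(config.n_sites):
        seq = fasta[protein_ids[site_protein_idx[s]]]
        center = site_position[s] - 1
        left = max(0, center - half)
        right = min(len(seq), center + half + 1)
        win = ("_" * (half - (center - left))
               + seq[left:right]
               + "_" * (half - (right - 1 - center)))
        windows.append(SiteWindow(win))

    localization = _draw_localization(config, config.n_sites, rng)
    site_level = 10.0 ** rng.normal(-0.5, config.site_level_log10_sd,
                                    config.n_sites)

    # --- intensities ---------------------------------------------------------
    n_chan = len(config.strains) * config.n_replicates * n_tp
    chan_meta = design.subset("N")  # same layout for PE
    strain_idx = np.array([list(config.strains).index(s)
                           for s in chan_meta["strain"]])
    rep_idx = chan_meta["replicate"].to_numpy() - 1
    tp_idx = np.array([config.timepoints.index(t)
                       for t in chan_meta["timepoint_min"]])

    chan_factor_n = np.exp2(rng.normal(0.0, config.channel_scale_sd_log2,
                                       n_chan))
    chan_factor_pe = np.exp2(rng.normal(0.0, config.channel_scale_sd_log2,
                                        n_chan))
    prot_batch = rng.normal(0.0, config.batch_effect_sd_log2 / np.sqrt(2),
                            (config.n_proteins, config.n_replicates))
    site_batch = rng.normal(0.0, config.batch_effect_sd_log2 / np.sqrt(2),
                            (config.n_sites, config.n_replicates))

    boost = 10.0 ** config.protein_boost_log10
    prot_true = baseline[:, None] * profiles[:, tp_idx] * boost
    prot_intensity = (
        prot_true
        * chan_factor_n[None, :]
        * np.exp2(prot_batch[:, rep_idx])
        * _lognormal_noise(config.noise_cv,
                           (config.n_proteins, n_chan), rng)
    )

    activity = np.ones((config.n_sites, n_chan))
    act_lookup: dict[tuple[str, str], np.ndarray] = {}
    for k in kinase_names:
        for strain in config.strains:
            act_lookup[(k, strain)] = np.asarray(
                config.kinases[k].activity[strain], dtype=float)
    for s in range(config.n_sites):
        kin = site_kinase[s]
        if kin:
            for j, strain in enumerate(config.strains):
                cols = strain_idx == j
                activity[s, cols] = act_lookup[(kin, strain)][tp_idx[cols]]

    site_true = (
        baseline[site_protein_idx][:, None]
        * profiles[site_protein_idx][:, tp_idx]
        * site_level[:, None]
        * activity
    )
    site_intensity = (
        site_true
        * chan_factor_pe[None, :]
        * np.exp2(site_batch[:, rep_idx])
        * _lognormal_noise(config.noise_cv, (config.n_sites, n_chan), rng)
    )

    # --- dropout -------------------------------------------------------------
    prot_zero = rng.random(prot_intensity.shape) < dropout_probability(
        prot_intensity, config)
    site_zero = rng.random(site_intensity.shape) < dropout_probability(
        site_intensity, config)
    prot_intensity = np.where(prot_zero, 0.0, prot_intensity)
    site_intensity = np.where(site_zero, 0.0, site_intensity)

    # --- assemble tables -----------------------------------------------------
    n_labels = design.channels(enrichment="N")
    pe_labels = design.channels(enrichment="PE")
    protein_matrix = pd.DataFrame(prot_intensity, index=protein_ids,
                                  columns=n_labels)
    protein_matrix.index.name = "protein_id"
    protein_meta = pd.DataFrame({
        "gene_name": [f"GEN{i:04d}" for i in range(config.n_proteins)],
        "is_contaminant": False,
        "is_reverse": False,
    }, index=protein_matrix.index)

    residues = [w.center for w in windows]
    site_ids = [f"{protein_ids[p]}_{r}{pos}" for p, r, pos in
                zip(site_protein_idx, residues, site_position)]
    phospho_matrix = pd.DataFrame(site_intensity, index=site_ids,
                                  columns=pe_labels)
    phospho_matrix.index.name = "site_id"
    phospho_meta = pd.DataFrame({
        "protein_id": [protein_ids[p] for p in site_protein_idx],
        "position": site_position,
        "residue": residues,
        "localization_prob": localization,
        "window": windows,
        "gene_name": [f"GEN{p:04d}" for p in site_protein_idx],
        "is_contaminant": False,
        "is_reverse": False,
    }, index=phospho_matrix.index)

    # decoy and contaminant rows exercise the flag filter
    n_rev = int(round(config.fraction_reverse * config.n_proteins))
    n_con = int(round(config.fraction_contaminant * config.n_proteins))
    decoy_rows = []
    for i in range(n_rev + n_con):
        decoy_rows.append(10.0 ** rng.normal(5.0, 0.5, n_chan))
    if decoy_rows:
        decoy_ids = ([f"REV__YSY{i:04d}" for i in range(n_rev)]
                     + [f"CON__Q{i:04d}" for i in range(n_con)])
        decoy_m = pd.DataFrame(np.asarray(decoy_rows), index=decoy_ids,
                               columns=n_labels)
        decoy_meta = pd.DataFrame({
            "gene_name": "",
            "is_contaminant": [False] * n_rev + [True] * n_con,
            "is_reverse": [True] * n_rev + [False] * n_con,
        }, index=decoy_m.index)
        protein_matrix = pd.concat([protein_matrix, decoy_m])
        protein_meta = pd.concat([protein_meta, decoy_meta])
        protein_matrix.index.name = "protein_id"

    # --- truth ---------------------------------------------------------------
    class_id = np.array(
        [kinase_names.index(k) + 1 if k else 0 for k in site_kinase])
    strain_diff = np.array([
        bool(k) and any(
            not np.allclose(act_lookup[(k, a)], act_lookup[(k, b)])
            for a in config.strains for b in config.strains
        )
        for k in site_kinase
    ])
    dynamic = np.array([
        bool(k) and max(act_lookup[(k, config.strains[0])]) > 1.0
        for k in site_kinase
    ])
    polo = [k for k in kinase_names
            if any(strain_diff[site_kinase == k])] or [""]
    bg_match = 0.0
    if kinase_names:
        from .motifs import match_site
        first_diff = next((k for k in kinase_names
                           if (site_kinase == k).any()
                           and strain_diff[site_kinase == k][0]), None)
        if first_diff:
            bg_windows = [w for w, k in zip(windows, site_kinase) if not k]
            bg_match = float(np.mean([
                match_site(w, patterns[first_diff]) for w in bg_windows
            ])) if bg_windows else 0.0
    truth_sites = pd.DataFrame({
        "protein_id": phospho_meta["protein_id"],
        "kinase": site_kinase,
        "class_id": class_id,
        "true_dynamic": dynamic,
        "true_strain_diff": strain_diff,
        "localization_prob": localization,
    }, index=phospho_matrix.index)
    truth_proteins = pd.DataFrame({
        "profile_class": prot_classes,
        "true_dynamic": prot_classes != 0,
    }, index=pd.Index(protein_ids, name="protein_id"))
    truth = SyntheticTruth(
        sites=truth_sites,
        proteins=truth_proteins,
        activities=act_lookup,
        summary={
            "background_match_rate": bg_match,
            "site_zero_rate": float(site_zero.mean()),
            "protein_zero_rate": float(prot_zero.mean()),
        },
    )
    return SyntheticDataset(
        design=design,
        protein_matrix=protein_matrix,
        protein_meta=protein_meta,
        phospho_matrix=phospho_matrix,
        phospho_meta=phospho_meta,
        truth=truth,
        fasta=fasta,
        config=config,
    )


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    sensitivity: float
    fdr: float
    tp: int
    fp: int
    fn: int


def evaluate_calls(called: pd.Series, truth_flags: pd.Series) -> RecoveryMetrics:
    """Sensitivity and FDR of boolean calls against planted truth.

    Metrics are computed over the call index (the analysed feature set);
    every called id must exist in the truth, otherwise the ids are
    misaligned and an error is raised.  FDR is 0 when nothing is called.
    """
    missing = called.index.difference(truth_flags.index)
    if len(missing):
        raise ValueError(f"calls contain ids absent from truth: "
                         f"{list(missing[:5])}")
    truth = truth_flags.reindex(called.index).astype(bool)
    called = called.astype(bool)
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return RecoveryMetrics(sensitivity=sens, fdr=fdr, tp=tp, fp=fp, fn=fn)


def clustering_ari(labels: pd.Series, truth_classes: pd.Series) -> float:
    """Adjusted Rand index between cluster labels and planted classes,
    over the clustered features (which must all carry truth labels)."""
    missing = labels.index.difference(truth_classes.index)
    if len(missing):
        raise ValueError(f"cluster labels contain ids absent from truth: "
                         f"{list(missing[:5])}")
    ref = truth_classes.reindex(labels.index)
    return float(adjusted_rand_score(ref.to_numpy(), labels.to_numpy()))


def activity_profile_correlation(
    cluster_profiles: pd.DataFrame,
    labels: pd.Series,
    truth: SyntheticTruth,
    truth_classes: pd.Series,
    strain: str = "wild_type",
) -> dict[str, float]:
    """Pearson correlation between each planted kinase's activity wave and
    the median profile of the cluster that captured most of its sites."""
    out = {}
    for (kinase, s), wave in truth.activities.items():
        if s != strain:
            continue
        members = truth_classes.index[truth_classes.eq(kinase)]
        members = members.intersection(labels.index)
        if len(members) == 0:
            out[kinase] = float("nan")
            continue
        top_cluster = labels.loc[members].mode().iloc[0]
        cluster_members = labels.index[labels == top_cluster]
        med = cluster_profiles.loc[cluster_members].median(axis=0).to_numpy()
        if np.std(med) == 0 or np.std(wave) == 0:
            out[kinase] = float("nan")
        else:
            out[kinase] = float(np.corrcoef(med, np.asarray(wave))[0, 1])
    return out


def evaluate_against_truth(
    strain_diff_calls: pd.Series,
    truth: SyntheticTruth,
    cluster_labels: pd.Series | None = None,
    cluster_profiles: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Bundle of recovery metrics for a pipeline run on synthetic data."""
    m = evaluate_calls(strain_diff_calls, truth.sites["true_strain_diff"])
    out = {
        "strain_diff_sensitivity": m.sensitivity,
        "strain_diff_fdr": m.fdr,
        "strain_diff_tp": float(m.tp),
        "strain_diff_fp": float(m.fp),
        "strain_diff_fn": float(m.fn),
    }
    if cluster_labels is not None:
        kin = truth.sites["kinase"].where(truth.sites["kinase"] != "", "none")
        out["cluster_ari"] = clustering_ari(cluster_labels, kin)
        if cluster_profiles is not None:
            corr = activity_profile_correlation(
                cluster_profiles, cluster_labels, truth, kin)
            for kinase, r in corr.items():
                out[f"profile_corr_{kinase}"] = r
    return out
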