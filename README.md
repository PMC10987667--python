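# phoswave

Analysis of multiplexed (TMT) phosphoproteome time courses, built around
the question of how kinase activities wave through the two meiotic
divisions of budding yeast: which phospho-sites rise and fall, which
kinase consensus motifs drive each temporal cluster, and which motif
variants distinguish sites that lose phosphorylation in a mutant.

It is written for proteomics analysts who have MaxQuant `proteinGroups`
and `Phospho (STY)Sites` tables from a reporter-ion experiment (two
strains x two replicates x a block-release timecourse, or replicate-only
arrest/inhibition designs) and want the complete downstream analysis as a
tested, scriptable library instead of a pile of one-off scripts.

## What it computes

* **Normalization.** Each reporter channel *j* is scaled by
  `median(all channels) / median(channel j)` (zeros treated as missing and
  restored); phospho-sites are normalized to their protein as
  `1000 * PE_ij / N_ij` on matched channels; replicate (batch) effects are
  removed per feature on the log2 scale and antilogged.
* **Filtering.** Contaminant/reverse flags; localization probability
  strictly > 0.75; proteins detected in >= 1 timepoint of every replicate
  of every strain; phospho-sites detected in >= 2 *consecutive*
  timepoints of every replicate, normalizable to protein at all
  timepoints.
* **Differential calling.** For each comparison (each timepoint vs t0,
  strain vs strain at matched timepoints, or arrest replicates), a
  feature is called changed when the replicate-median fold change exceeds
  1.5 (or falls below 1/1.5) *and* Welch's t-test on the replicate
  intensities gives p < 0.05. All-zero-vs-detected comparisons may pass
  the fold-change rule by construction ("zero rescue"); their infinite
  fold changes are imputed with the dataset minimum.
* **Clustering.** Ward linkage on Euclidean distances with un-squared
  heights (R's `ward.D2` semantics) over mean-scaled, replicate-averaged
  profiles; the cluster count comes from a deterministic elbow rule on
  the within-group sum-of-squares curve, and is always overridable.
* **Motifs.** A 12-kinase consensus table (e.g. `[ST]*Px[KR]` for strict
  Cdk, `[DEN]x[ST]*` for Polo kinase), a positional matcher over
  +/-15-residue windows, Fisher exact enrichment of motifs per cluster,
  IceLogo-style percent-difference residue logos, single-offset
  sub-motif discovery (e.g. finding the +1 F of `[DEN]x[ST]*F`), and a
  plain `S[ST]P` polo-box-binding scan over protein sequences.
* **Over-representation.** Upper-tail hypergeometric tests of annotation
  terms with Benjamini-Hochberg q-values.
* **Synthetic data.** A generator that emulates the whole experiment —
  planted kinase-activity waves (one biphasic, one meiosis-I-only wave
  abolished in the mutant, one late wave), log-normal noise, channel and
  batch effects, intensity-dependent dropout, localization scores, decoy
  rows — with complete ground truth for end-to-end validation.

## Worked example

```python
from phoswave import SimConfig, generate_dataset, run_timecourse

dataset = generate_dataset(SimConfig(seed=1))
result = run_timecourse(dataset.design, dataset.protein_matrix,
                        dataset.protein_meta, dataset.phospho_matrix,
                        dataset.phospho_meta)
for stage, count in result.stage_counts.items():
    print(f"{stage:>28}  {count}")
print(result.submotif[["residue", "fg_pct", "bg_pct", "p_value"]].head(1))
```

prints

```
              proteins_input  1040
                 sites_input  2000
       proteins_flag_removed  40
          sites_flag_removed  0
              proteins_final  1000
                 sites_final  1583
            proteins_dynamic  161
               sites_dynamic  555
      sites_strain_different  295
    sites_zero_mean_excluded  0
                  clusters_k  2

  residue     fg_pct     bg_pct       p_value
0       F  84.146341  29.104478  3.955933e-19
```

Reading the numbers: of 2000 simulated sites, 1583 survive the
localization, detection and normalizability rules; 555 are called dynamic
versus prophase t0 and 295 differ between the strains at some matched
timepoint. The sub-motif table is the punchline of the analysis: among
Polo-consensus (`[DEN]x[ST]*`) sites with reduced phosphorylation in the
mutant, 84% carry phenylalanine at +1 versus 29% of unchanged sites
(Fisher p ~ 4e-19) — the generator planted exactly this `[DEN]x[ST]*F`
class, and the pipeline recovers it.

The same analysis runs from the shell on written tables:

```sh
phoswave simulate --out sim --seed 1
phoswave run run.yaml          # declarative config; see docs/methods.md
phoswave scan-sstp sim/proteins.fasta
```

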