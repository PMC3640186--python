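# landuse16s

A tested re-implementation of a paired-read 16S rRNA amplicon analysis that
screens soil microbial genera for *agricultural land-use signatures* — taxa
whose relative abundance correlates with agricultural management consistently
across independent study sites.  The motivating biology: ammonia-oxidizing
archaea of the genus *Ca.* Nitrososphaera respond positively to the higher pH
(and therefore higher free NH3) of limed, fertilized agricultural soils, while
*Bradyrhizobium* responds negatively, making the two genera inverse indicators
of land use.

The package contains the full chain as importable, unit-tested modules:

| stage | module | what it does |
|---|---|---|
| synthetic study | `landuse16s.simulate` | toy reference taxonomy with controlled divergence, soil covariates, communities with planted pH effects, barcoded paired FASTQ reads |
| read processing | `landuse16s.reads` | exact-barcode demultiplexing, 11-base primer removal, maximum-sum quality trimming |
| classification | `landuse16s.classify`, `landuse16s.align` | local alignment (+1/−1/−2) of each mate against every reference, 80% length-fraction filter, rank identity thresholds (80/80/90/90/90/95/99% for domain…species), LCA fallback for discordant mates |
| soil chemistry | `landuse16s.soil` | NH3 from NH4⁺-N and pH via Henderson–Hasselbalch speciation (pKa 9.23); SOM = 1.72 × %OC |
| statistics | `landuse16s.stats` | Spearman rho (exact permutation p for n ≤ 8), arcsine-square-root transform, one-/two-way ANOVA, 0.05% abundance filter, 3-set Venn partition, cross-site signature rule, fold changes |
| orchestration | `landuse16s.pipeline`, `landuse16s.cli` | in-memory study runner, file-based pipeline, `landuse16s` CLI with per-stage subcommands |

The model at the core of the statistics: a genus *g* is a **signature** of land
use iff, at *every* site where it passes the site-wide abundance floor
(≥ 0.05% of trimmed read pairs), Spearman's rank correlation of its relative
abundance with the land-use indicator (agricultural = 1) satisfies
|ρ| ≥ 0.5 with p ≤ 0.001, with a consistent sign.  Relative abundance of genus
*g* in sample *j* is `n_gj / N_j` where `N_j` is the number of read pairs
surviving trimming in sample *j* (not the number classified).  Free ammonia is
derived from measured ammoniacal N as

    NH3-N = NH4-N · 10^(pH−9.23) / (1 + 10^(pH−9.23))

## Worked example

```
$ landuse16s all --outdir run --seed 1
```

simulates a 3-site × 2-land-use × 16-sample study (400 read pairs per sample,
0.5%/base substitution errors) and runs the full pipeline.  The tail of the
printed report from that exact command:

```
== land-use signature genera (|rho| >= 0.5, p <= 0.001 at all sites) ==
Bradyrhizobium: negative (BRR: -0.81, EAA: -0.82, KBS: -0.86)
Nitrososphaera: positive (BRR: +0.87, EAA: +0.85, KBS: +0.85)

== Venn of abundant genera (>= 0.05% site-wide) ==
...
BRR&EAA&KBS: 12
shared fraction (triple / union): 1.000
```

Both planted effects are recovered: the archaeal focal genus is positively,
and the rhizobial focal genus negatively, correlated with agriculture at all
three sites; all 12 toy genera are abundant enough to appear at every site, so
the triple Venn region holds the whole genus set.  The per-site agricultural
vs non-agricultural fold changes of the two focal genera (5–7×, see
`analysis/04_landuse_anova.py` output in `results/anova_oneway.tsv`) bracket
the 2–7× range reported for real soils.

The numbered scripts under `analysis/` run the same chain as a narrative:
`01_simulate_study.py` → `02_run_pipeline.py` (summary tables into
`results/`), `03_soil_speciation.py` (speciation on the published plot means),
`04_landuse_anova.py`, `05_signature_robustness.py` (multi-seed recovery).

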