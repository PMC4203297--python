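# pstsim

Coalescent-simulation hypothesis testing of speciation models with the
**percentage sorted trees (PST)** statistic.

## The problem

When did two sister species split, and did one of them start from a
handful of founders?  Multilocus nuclear data answer this only through
the lens of *incomplete lineage sorting*: gene trees sampled from a
recent split still interleave the two species, while gene trees from an
old split are reciprocally monophyletic.  `pstsim` implements a
simulation-based test of explicit speciation scenarios built on this
signal, developed around a 14-nuclear-locus study of the Mojave
fringe-toed lizard (*Uma scoparia*) and the *U. notata* species complex,
together with the supporting machinery that study needs: summary
statistics, isolation-with-migration (IM) parameter conversion, and
nested-model ranking.

## The method

For each candidate two-population isolation model (effective sizes
N&#8321;, N&#8322;, N&#8320; for the two species and their ancestor,
divergence time *T*, optionally a founder epoch of size *N*<sub>f</sub>
covering the oldest 5% of the second species' branch):

1. simulate a null distribution of gene trees (70 + 15 sampled
   haplotypes) under the neutral coalescent (msprime);
2. evolve a 500-bp HKY sequence matrix along each tree, with the branch
   scaling calibrated so simulated between-species divergence matches
   the observed data;
3. reconstruct each tree by unweighted parsimony (stepwise addition +
   NNI, a bitset Fitch kernel), as one would for real data;
4. compute **Slatkin's s** — the minimum number of changes of the
   species label on the tree; *s* = 1 means at least one species is
   monophyletic ("sorted");
5. the **PST** of a tree set is the percentage with *s* = 1.  An
   observed PST (from real gene trees) is tested against a model's
   expected PST with a chi-square test that treats percentages as counts
   out of 100 (1 df): χ² = (o − 100p)² / (100·p·(1−p)), rejecting at
   *P* < 0.05.

A power analysis (`power_analysis`) measures how often pseudo-observed
14-locus datasets generated under one model reject another.

## Worked example

```python
from pstsim import (build_model_registry, tally_s_distribution,
                    NullPipeline, pst_chi_square, rejection_interval)

registry = build_model_registry()          # models 1a..4b of the study
null = tally_s_distribution(registry["2a"], 200,
                            NullPipeline(mode="truetree"), seed=42)
print(null.pst)                            # 69.0
print(dict(sorted(null.counts.items())))   # {1: 138, 2: 58, 3: 4}

test = pst_chi_square(50.0, null.sorted_proportion, alpha=0.05,
                      n_null=null.n_trees)
print(round(test.chi_square, 3), test.rejected)   # 16.877 True
print(rejection_interval(50.0))            # (41, 59)
```

Reading: under the 1.0-Ma constant-size model, 69% of simulated
genealogies are sorted (*s* = 1); an observed PST of 50% (7 of 14 loci
sorted, as in the study's maximum-likelihood gene trees) rejects that
expectation (χ² = 16.9, *P* < 0.001), and more generally rejects every
expected PST outside 41–59%.

The same pipeline is scriptable from the shell:

```bash
pstsim make-synthetic --model 2a --seed 17 --out data/
pstsim simulate-null --model 2a --reps 1000 --seed 1 --out null2a
pstsim pst-test --trees locus1.nwk --trees locus2.nwk \
    --popmap data/popmap.tsv --null null2a.s.tsv
pstsim summarize --fasta data/BDNF.fasta --popmap data/popmap.tsv
pstsim rank-models --table nested_models.tsv
```

`pstsim.datasets` ships the study's printed summary tables (per-locus
diversity, SNP tallies, IM estimates, nested-model fits) so the
diversity comparisons (mean π 0.468% vs 0.126%, Welch *P* = 0.006), the
SNP frequencies (200/60,836 bp = 0.33%) and the AIC/LRT ranking
(best nested model 2LLR = 3.02) can all be recomputed from source.

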