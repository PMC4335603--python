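# transpoly

Footprints of ancient balanced trans-species polymorphisms in two-species
variation data: analytic theory, coalescent simulators, and a scanner.

## The problem

When balancing selection maintains a biallelic polymorphism for longer than
the split between two species, both species inherit the *same* polymorphism
identical by descent.  At the selected site the gene genealogy then clusters
by allele instead of by species, and — because of linkage — a short
*ancestral segment* around the site shares that unusual genealogy.  Inside
it there can be additional shared neutral SNPs in strong LD with the same
alleles coupled in both species, and no fixed differences.  Outside a scan
context the same shared-SNP signal can arise from recurrent mutation at
hypermutable (CpG) sites, so the question is quantitative: how long is the
segment, how many shared SNPs does it carry, how strong is their LD, and how
often does neutrality fake all three?

`transpoly` implements the model for two species of diploid size $N_e$ that
split $T$ generations ago from an ancestor of size $N_a$, with a balanced
polymorphism at frequency $p$ (derived allele A1), age $T_S$ generations
beyond the end of the four-to-two-lineage coalescent stage, and per-bp
recombination and mutation rates $r$ and $\mu$.

Core results (all in the structured-coalescent framework where allelic
classes act as demes and class-switching recombination is the migration):

* **Segment length.** On each side of the selected site the length $X$ (in
  Morgans) of the ancestral segment satisfies
  $X \mid t \sim \mathrm{Exp}(2(T+t))$ with $t=\max(t_1,t_2)$,
  $t_1\sim\mathrm{Exp}(1/(2N_a p))$, $t_2\sim\mathrm{Exp}(1/(2N_a q))$,
  giving the closed-form survival
  $S(x) = e^{-2Tx}\left[\frac{a}{a+2x}+\frac{b}{b+2x}-\frac{a+b}{a+b+2x}\right]$.
  The total length is the self-convolution of the one-sided law.
* **Shared SNPs.** The expected number of shared neutral SNPs at distance
  $d$ is $2\mu\,E[T_B(d)]$, where $E[T_B]$ — the coalescent time of the two
  stage-III lineages — comes from a two-deme island model (infinitely old
  polymorphism) or a per-generation Markov chain over states
  $(1,1),(0,2),(2,0),(*)$ with a forced coalescence of derived-background
  pairs when the polymorphism arose (finite age $T_S$).
* **LD.** For four chromosomes (one per class per species) shared SNPs are
  in perfect LD ($r^2=1$) with the selected site; for larger samples LD
  decays through stage-I class switching (retention probability $R_n$).
* **Null model.** A neutral two-species coalescent with finite-sites
  CpG-hypermutable mutation quantifies how often recurrent mutation creates
  close shared-SNP pairs and what their $r^2$ looks like.

## Worked example

```bash
transpoly length --Na 50000 --T 250000 --p 0.5 --r 1.2e-8 \
    --quantiles 0.5,0.95 --out length.tsv && cat length.tsv
```

```
#statistic	morgans	bp
mean	1.57718e-06	131.431
q0.5	1.07686e-06	89.7384
q0.95	4.78121e-06	398.434
```

For human–chimpanzee parameters the ancestral segment extends on average
131 bp on each side of the selected site (263 bp total), with a 95% quantile
near 400 bp: the entire footprint of millions of years of balancing
selection is confined to a few hundred base pairs.  The same command with
`--Na 1e6 --T 2e7` (a *Drosophila*-like regime) gives a mean of ~2 bp — the
split must be old enough to rule out lineage sorting but young enough
($T \ll 1/r$) to leave a detectable segment.

Other entry points: `transpoly coaltime` (expected between-class coalescent
times, numeric chain vs closed-form approximation), `transpoly shared-snps`
(expected shared-SNP count vs polymorphism age), `transpoly simulate`
(conditional structured-coalescent replicates, ms-style output),
`transpoly null` (recurrent-mutation null summary), `transpoly scan
--vcf1 --vcf2 [--fasta]` (shared-SNP clusters, spans, coupling phases, CpG
flags from two phased per-species VCFs), and `transpoly fixtures`
(deterministic toy datasets).

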