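# agarcode

DNA-barcode marker evaluation and diagnostic-locus classification for
*Aquilaria* (agarwood).

Agarwood — the resinous wood of infected *Aquilaria* trees — is traded
worldwide, but products on the market are nearly impossible to assign to a
species or region by morphology alone. `agarcode` implements the molecular
identification workflow used for this problem end to end:

1. **Marker evaluation.** For each candidate barcode (matK, ITS2, rbcL,
   trnL-trnF): Kimura 2-parameter (K2P) pairwise distances with pairwise
   deletion of gaps/ambiguities,

   `d = -1/2 · ln((1 - 2P - Q)·sqrt(1 - 2Q))`

   where *P* and *Q* are the transition and transversion proportions;
   intra- vs interspecific distance summaries; the barcode-gap rule
   (mean interspecific ≥ *r* × mean intraspecific, classically *r* = 10);
   Welch *t* and Kruskal–Wallis comparisons between markers; Neighbor-Joining
   trees with column-resampling bootstrap and per-species monophyly.
2. **Haplotypes.** DnaSP-style collapsing over a gap/ambiguity mask, with
   segregating-site counts and SNP% per species.
3. **Median-Joining networks.** Haplotype graphs with inferred median
   vectors, minimizing total substitution length; substitution-count edge
   weights; TSV/GraphML/dot export.
4. **Diagnostic-locus classification.** A character-based key over fixed
   alignment positions (matK +249=C → Chinese mainland origin; +435=G and
   +684=T jointly → *A. sinensis*; trnL-trnF +173/+183/+200 refine the
   origin cluster). Unknown, unaligned queries are mapped onto bundled
   reference frames by pairwise alignment (either orientation) before the
   key is read, and panels of samples are classified into biogeographic
   pedigrees (C1/C2 Chinese, B Indonesian, A Indochinese).
5. **Synthetic benchmarks.** A generator for labeled marker alignments with
   known truth — per-species haplotype structure, planted diagnostic sites,
   κ-biased transition/transversion process, poly(T) slippage windows — so
   every stage is testable without any downloads.

## Worked example

```python
from agarcode import (SynthConfig, SpeciesSpec, generate_alignment,
                      distance_matrix, summarize_distances, barcode_gap)

cfg = SynthConfig(
    marker="matK", length=600,
    species=tuple(SpeciesSpec(f"sp{i}", 12, 12) for i in range(1, 7)),
    theta_intra=0.0012, theta_inter=0.0083, seed=401,
)
aln, truth = generate_alignment(cfg)
s = summarize_distances(distance_matrix(aln), list(aln.species), marker="matK")
print(f"intra={s.intra_mean:.4f} inter={s.inter_mean:.4f} "
      f"ratio={s.gap_ratio:.1f} passes(r=5)={barcode_gap(s, r=5).passes}")
```

prints

```
intra=0.0008 inter=0.0098 ratio=11.7 passes(r=5)=True
```

i.e. a matK-like marker (low intraspecific, ~6–7× higher interspecific
divergence) clears the operational barcode-gap criterion at r = 5, while an
rbcL-like marker (inter ≈ intra) does not.

Classifying an unknown sample:

```python
from agarcode import classify_sample
res = classify_sample(matk_query)          # an unaligned matK sequence
print(res.species_call, res.origin_call, res.pedigree)
# e.g. "A. sinensis", "Chinese mainland", "C1/C2"
```

There is also a CLI (`agarcode evaluate / haplotypes / network / classify /
simulate`); run `agarcode --help`.

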