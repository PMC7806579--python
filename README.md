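# adductgraph

Graph-based adduct annotation of positive-mode, high-resolution ESI-MS1
centroid spectra of small molecules.

Electrospray rarely produces only the protonated molecule. A single analyte
commonly appears as [M+H]⁺ together with sodium and potassium adducts,
replacement series [M+*n*Na−(*n*−1)H]⁺, ammonia and water losses, and proton-
bound multimers [2M+H]⁺, [3M+H]⁺ — and in crowded LC regions or flow-injection
spectra several analytes contribute at once. `adductgraph` untangles such
spectra without relying on chromatography: it is aimed at metabolomics and
small-molecule LC/FIA-MS users who need to know which peaks are protonated
molecules and which are merely related ions.

## Method

For a spectrum with peaks *p₁ … pₙ* (m/z, intensity):

1. **Filter.** Peaks below an absolute intensity floor (default 500 cps) or
   below 1 % of the base peak are flagged; ¹³C isotope satellites
   (+1.003355 Da per step, intensity 1–100 % of the monoisotopic peak, z = 1
   only) are removed by a greedy envelope walk.
2. **Graph.** Every retained peak is treated as a putative [M+H]⁺ of neutral
   mass *M = m/z − 1.007276*. For each species in a small combinable
   annotation set — by default NH₄⁺, Na⁺, K⁺ adducts, NH₃ and H₂O losses,
   dimers and trimers, stacked up to two deltas deep — any other peak within
   an absolute tolerance (default 10 mmu) of ion_mz(*M*, species) receives a
   directed edge labelled with the species and its signed mass error. A
   ±17.0265 shift is ambiguous (ammonium adduct *or* ammonia loss) and yields
   a bidirectional edge.
3. **Cluster & rank.** Weakly connected components are clusters of related
   ions. Within each cluster every peak's *explained TIC* is the summed
   intensity of itself and the peaks it annotates; the peak with the largest
   explained TIC is the cluster's [M+H]⁺ candidate, ties resolved by
   connectivity (number of peaks explained besides itself). Each candidate is
   qualified by **CGC** (ions in the cluster), **CIC** (% of spectrum TIC in
   the cluster) and **CCC** (% of the retained peak count in the cluster).
   Singleton ions are listed separately as unexplained putatives, and peaks
   matching *M*ᴀ + *M*ʙ + H⁺ for a candidate pair are flagged as possible
   heterodimers.

All arithmetic uses monoisotopic NIST element masses with electron-mass
bookkeeping (e.g. Na−H = 21.9819, K−H = 37.9559, Ca−2H = 37.9469 Da).

## Worked example

The package ships a reconstructed 19-peak LC spectrum in which l-proline,
creatine (with its creatinine water-loss twin) and homocitrulline co-elute:

```
$ adductgraph annotate src/adductgraph/data/fixtures/lc_proline_mix.mgf --out demo
INFO LC mix 1.35 min (reconstructed): 19 peaks, 19 retained, 3 clusters, 3 candidates, 1 singletons
1 spectra annotated: 3 cluster candidates, 1 singleton putatives (4 putative [M+H]+ in total)
```

`demo/candidates.tsv` (abridged):

| candidate_mz | neutral_mass | connectivity | CGC | CIC % | CCC % |
|---|---|---|---|---|---|
| 132.0768 | 131.0695 | 6 | 7 | 37.0 | 36.8 |
| 116.0706 | 115.0633 | 4 | 5 | 42.0 | 26.3 |
| 190.1195 | 189.1122 | 4 | 6 | 20.0 | 31.6 |

Nineteen putative protonated molecules collapse to four: the candidates are
creatine (132.0768), proline (116.0706) and homocitrulline (190.1195), plus
one background singleton at 104.1070. The neutral masses 131.0695 and
115.0633 identify creatine and proline directly. The companion
`annotations.tsv` lists every edge with its signed error in mmu — e.g.
`116.0706 → 176.0100 [M+Na+K-H]+ +1.57 mmu` shows a trigonelline [M+K]⁺ ion
being absorbed into the proline cluster, and
`132.0768 → 114.0662 [M+H-H2O]+ -0.04 mmu` shows creatinine's protonated form
being (mis)read as a water loss from creatine — two ambiguities that only
chromatographic profiles can settle.

Other entry points: `adductgraph convert` turns a chromatographic feature
table (CSV with `mz, rt, into, pcgroup` columns) into pseudo-spectrum mgf;
`adductgraph simulate` generates seeded, ground-truthed synthetic spectra from
a YAML compound list.

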