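# Methods

## Model and assumptions

`adductgraph` annotates centroided, positive-mode ESI-MS1 spectra of
low-molecular-weight analytes. Its working assumptions are:

* **Singly charged ions only.** Multiply charged species are unlikely for
  small molecules and are not modelled; deisotoping and all m/z arithmetic
  assume z = +1.
* **Mass accuracy is consistent within a spectrum.** Relations between ions
  of one analyte are therefore detectable by an absolute m/z-shift match,
  and the signed mass error of each match is itself informative (a cluster
  of consistently shifted errors suggests a wrong charge agent, e.g. Ca
  instead of K).
* **Spectra may be mixtures.** No chromatographic purity is assumed; the
  clustering step separates co-occurring analytes by their mass
  relationships alone, and the documented failure modes (below) are exactly
  the cases where mass alone cannot decide.

An ion species is represented symbolically as a multimer order *n* plus a
multiset of elementary composition changes applied to the protonated frame
[nM+H]⁺: metal/proton replacements (Na−H, K−H, Ca−2H), neutral adduction
(+NH₃), and neutral losses (−H₂O, −NH₃). The m/z of a species for neutral
monoisotopic mass *M* is *n·M* + proton + Σ delta masses, with the proton
constant 1.007276 Da (H minus one electron) carrying the charge bookkeeping.
Element masses are the standard NIST monoisotopic values; electron mass
0.000549 Da. Two derivations with the same net atomic composition are the
same species (an ammonia gain followed by an ammonia loss is [M+H]⁺).

## The species closure and its caps

The default annotation set contains three adducts (ammonium, sodium,
potassium), two neutral losses (ammonia, water), and dimers and trimers.
Rather than enumerating a long list of empirical mass differences, the set is
*combined*: all distinct species reachable by stacking at most `max_depth`
base deltas (default 2) are generated once per run, each delta further capped
by its own multiplicity:

| delta | mass (Da) | cap | rationale |
|---|---|---|---|
| Na−H | +21.9819 | 3 | replacement scales with labile protons |
| K−H | +37.9559 | 3 | as Na−H |
| Ca−2H | +37.9469 | 2 | divalent replacement; not in the default set |
| +NH₃ | +17.0265 | 1 | a second ammonium adduction is essentially unobserved |
| −H₂O | −18.0106 | 2 | consecutive water losses occur |
| −NH₃ | −17.0265 | 1 | double ammonia loss is rare; see below |

Depth 2 covers every combination species seen in routine positive-mode work
([M+2Na−H]⁺, [M+Na+K−H]⁺, [M+Na+NH₃]⁺, [M+K−H₂O]⁺, [M+H−2H₂O]⁺,
[M+H−NH₃−H₂O]⁺). Deeper stacks buy very little and create spurious
tunnels between unrelated analytes — the three-delta combination K−H₂O−NH₃
is only 2.9188 Da, small enough to bridge co-eluting compounds of similar
mass — so depth 3+ is available per run (`annotation.max_depth`) but is not
the default. The calcium replacement is likewise shipped in the registry but
not in the default set; it exists for the interactive re-interpretation
workflow in which trimer ions with consistently poor potassium errors
(~−7 mmu) re-annotate cleanly as [3M+Ca−H]⁺ forms (~+2 mmu, the Ca/K
difference being 9.5 mmu with the commonly quoted constants, 9.0 mmu with the
element-table value used here).

Matching uses an absolute tolerance, default 10 mmu; a ppm mode was
considered and rejected because the instruments targeted here drift in
absolute rather than relative terms over the 80–900 m/z range of interest.

## Ranking conventions

The explained set of a peak is itself plus its *direct* annotation targets
(bidirectional ±NH₃ edges traversable both ways). One-hop counting, rather
than full reachability, is deliberate: under transitive closure the two ends
of a bidirectional edge always explain identical sets, which would make the
documented connectivity tie-break between an [M+H]⁺ and its [M+H−NH₃]⁺
fragment impossible, and one-hop counting matches the reference connectivity
figures this implementation reproduces. Connectivity is self-exclusive (a
peak explaining two others has connectivity 2; a leaf has 0); ties are
invariant to that ±1 choice. CGC counts all cluster members.

Tie-breaking order: explained TIC, connectivity, lowest summed |mass error|
over outgoing edges, lowest m/z. The last two are implementation choices (no
published convention exists); lowest-m/z-last guarantees determinism, and in
the genuinely ambiguous two-peak ±NH₃ cluster it selects the lighter ion,
which is the protonated molecule under the adduct reading.

CIC/CCC denominators count the post-deisotoping retained peaks, consistent
with reporting coverage of the filtered spectrum; singletons are included in
the denominators, so CIC and CCC sum to 100 % over the clusters of a
spectrum. Every ordering in the pipeline (cluster ids, table rows, summation
order) is sorted by m/z, so repeated runs are byte-identical.

## Filters

Thresholds: absolute floor 500 cps and 1 % of the base peak, the base peak
being taken over the peaks surviving the m/z window and any earlier flags —
this makes the intensity rules commute and the filter idempotent. Removed
peaks are flagged, never deleted, so reports can display them.

Deisotoping walks retained peaks from light to heavy; each unclaimed peak
starts an envelope and claims contiguous companions at +k·1.003355 Da within
the isotope tolerance whose ratio to the envelope head lies in 1–100 %. The
ratio is measured against the monoisotopic head (not the previous isotope);
the head of an envelope is always retained, and a claimed isotope can never
start an envelope. Monoisotopic validation vetoes an [M+H]⁺ reading for any
peak that could itself be the +1 isotope of a peak one spacing below.

## Synthetic data: what it emulates and what it does not

The generator produces centroid spectra from compound specifications (name,
formula, base intensity, species profile), with Gaussian m/z jitter,
proportional intensity noise, optional ¹³C satellites (+1 abundance
0.011 × carbon count × n — adequate for filter testing, not for
quantitation), and uniform background peaks; a truth map records every
non-noise peak. Fixed seed ⇒ identical output.

Random recovery mixtures draw 1–5 compounds from a 20-metabolite library
under a *non-interference* condition enforced by construction: subsets are
redrawn until no emitted ion of one compound falls within tolerance (plus a
4σ jitter guard) of any closure target of another compound's putative
[M+H]⁺ readings, and no cross-compound pair sits within one or two ¹³C
spacings (which could trip the deisotoper). Background positions are screened
the same way, so noise adds nodes but never relations. Two profile rules make
exact recovery a well-posed target: the ammonium adduct is excluded from
random profiles (a ±NH₃-only cluster is direction-ambiguous on mass alone, so
"the" right answer does not exist), and every profile includes at least one
monomer-frame partner (an n-mer match amplifies the [M+H]⁺ jitter n-fold, so
a trimer-only profile can drop out of tolerance at realistic 2-mmu jitter).

What passing these tests does **not** show about real data: real spectra have
correlated calibration error rather than independent jitter, chemical noise
that is related to the analytes, detector saturation, and co-eluting isomers;
the non-interference condition is precisely the regime where annotation is
easy. The worked-example fixtures probe the opposite regime (deliberate
interference), and the documented failure modes are asserted as failures.

### Worked-example fixtures

Two deterministic fixtures reconstruct reference spectra from known
formulas and reported m/z values: a 19-peak crowded LC spectrum (clusters of
5 proline / 7 creatine / 6 homocitrulline ions plus a singleton) and a
33-peak FIA proline spectrum (partition 13+4+2+2+2+10, describable as six
clusters if the singleton set counts as one group). Peak
intensities are not part of the reference record, so the fixtures solve them
from the reported ordinal facts: base-peak identity, cluster intensity coverages (61/42/37/20 %
— design targets of the fixtures, not independent reproductions), and the
exact explained-TIC tie between the homocitrulline [M+H]⁺ (190.1195) and its
ammonia-loss fragment (173.0922), resolved in favour of 190.1195 by
connectivity 4 vs 3. Each row in the fixture tables carries the constraint it
satisfies; the fixtures are also shipped as mgf + truth TSV package data and
a test pins the shipped files to the generator output.

## Known limitations

* Clusters of two ions related by ±17.027 Da remain direction-ambiguous;
  both readings are reported on a bidirectional edge.
* Analyte pairs differing by exactly a closure delta (creatine/creatinine at
  18.0106 Da; a trigonelline [M+K]⁺ falling 2.4 mmu from a proline
  [M+Na+K−H]⁺) merge into one cluster and the minor analyte is absorbed as a
  fragment or replacement form; a regression test asserts this documented
  wrong answer. Extracted ion chromatograms, outside this package's scope,
  are the stated remedy.
* Heterodimer detection is diagnostic only and considers candidate pairs,
  not arbitrary peak pairs.
* Negative mode has configuration slots but no shipped annotation set;
  multiply charged ions are out of scope.
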