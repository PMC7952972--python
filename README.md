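# pgtcnv

Low-pass single-blastomere copy-number analysis and embryo classification
for day-3 preimplantation genetic testing (PGT) of structural-rearrangement
carriers.

## The problem

Couples carrying a balanced chromosomal rearrangement — a reciprocal
translocation t(A;B), a Robertsonian translocation rob(A;B), or an
inversion — produce a large fraction of chromosomally unbalanced embryos
through malsegregation of the meiotic multivalent. PGT screens one
biopsied blastomere per cleavage-stage embryo by low-pass whole-genome
sequencing (~3 million single-end 55 bp reads, ≈0.04× depth), counts reads
in 1 Mb bins, and calls whole-chromosome and segmental copy-number changes:
a 2→3 copy gain raises the normalized bin signal by 50%, a 2→1 loss lowers
it by 50%, and intermediate shifts indicate mosaicism (fraction
f = |c − 2|; embryos with f > 40% are not transferred).

`pgtcnv` implements that analysis end to end, together with the genetics
around it:

- **karyotype** — ISCN parsing (`t`, `rob`/`der(q10;q10)`, `inv`, `del`,
  `dup`, `ins`) and band→coordinate resolution on a bundled
  hg19-compatible cytoband table;
- **meiosis** — enumeration of carrier gamete classes with exact
  `Fraction` weights: 2:2 / 3:1 / 4:0 quadrivalent segregation for
  reciprocal translocations (18-type counseling convention by default,
  so the balanced mass per carrier is 2/18 = 1/9 and a double-carrier
  couple has (1/9)² = 1/81 euploid odds), trivalent segregation for
  Robertsonians, recombinant/non-recombinant classes for inversions;
- **simulate** — a MALBAC-like count simulator with GC bias,
  negative-binomial overdispersion, dropout, whole-sample failure (5.7%),
  de novo and mosaic aneuploidies, and full ground truth;
- **cnvcall** — QC (read yield + MAPD), reference-panel and GC
  normalization, recursive binary-split segmentation, integer and mosaic
  copy-number calling; also exposed as a scikit-learn style estimator
  `CopyNumberCaller` (`fit` = build panel, `predict` = call);
- **classify** — five categories: I parental-rearrangement-related
  abnormalities only, II de novo only, III both, IV multiple aneuploid
  chromosomes (MAC, ≥3), V normal/balanced (the only transferable class);
- **cohort** — per-group rate tables formatted `x.y(n/d)`, chi-square and
  Fisher's exact contrasts, per-cycle clinical outcome rates.

## Worked example

```python
import pgtcnv as P

m = P.load_cytoband_map()

# a couple in which both partners carry a reciprocal translocation
km = P.resolve_breakpoints(P.parse_karyotype("46,XX,t(2;8)(q24;p22)"), m)
kf = P.resolve_breakpoints(P.parse_karyotype("46,XY,t(11;22)(q23;q11.2)"), m)
print(P.couple_euploid_probability(km, kf, m))      # -> 1/81

# simulate a blastomere with a 4.6 Mb maternal deletion in 21q22.3
import numpy as np
from pgtcnv.meiosis import ImbalanceRegion
grid = P.build_bin_grid(m, seed=0)
cfg = P.SimulationConfig()
rng = np.random.default_rng(7)
panel = P.build_reference(
    [P.simulate_blastomere_counts([], "XX" if i % 2 else "XY", grid, cfg,
                                  rng, sample_id=f"n{i}") for i in range(20)],
    grid)
band = m.band("21", "q22.3")
dele = [ImbalanceRegion("21", band.start + 400_000,
                        band.start + 5_000_000, -1)]
c = P.simulate_blastomere_counts(dele, "XX", grid, cfg, 3, sample_id="e1")
calls = P.call_sample(c, panel, grid)
for s in calls.segments:
    print(s.chrom, s.start, s.end, "call", s.call, "size", s.size_mb, "Mb")
# -> 21 43000000 48129895 call 1 size 5.129895 Mb

km_del = P.resolve_breakpoints(P.parse_karyotype("46,XX,del(21)(q22.3)"), m)
cls = P.classify_embryo(calls, km_del, P.parse_karyotype("46,XY"), m)
print(cls.category, cls.transferable)               # -> I False
```

The printed `1/81` is the couple's theoretical euploid-embryo probability
(each carrier contributes a 1/9 balanced-gamete mass). The called loss
segment recovers the simulated deletion to 1 Mb bin resolution, and the
embryo is classified category I (abnormality matching the parental
rearrangement) and blocked from transfer.

An end-to-end cohort run is available from the shell:

```bash
pgtcnv run --config demo.yaml --out report.json
```

with a YAML config listing the groups (label, parental karyotypes, embryo
counts), simulation/caller/classifier settings and a seed; the report
embeds the resolved config, per-embryo calls and classifications, and the
per-group rate table.

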