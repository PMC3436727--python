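# compositemap

Construction of **composite (reference) genetic linkage maps** by merging
independently built component maps — with full QC statistics and a synthetic
multi-pedigree data generator for end-to-end validation.

## The problem

A genetic linkage map orders DNA markers along chromosomes in recombination
units (centiMorgans, cM). High-density maps built in individual mapping
pedigrees (e.g. DArT + microsatellite maps in *Eucalyptus*) each capture only
the markers polymorphic in that pedigree, and joint re-analysis of the raw
segregation data across many large families is computationally infeasible in
standard mapping software. A *composite map* sidesteps this by merging
markers from several finished maps into one reference map, using the markers
shared between maps (anchor or bridging loci) to align them. The result is a
single high-density reference that lets markers mapped in different
pedigrees be placed relative to each other — for QTL comparison, genome
assembly anchoring and marker lookup.

Intended users are geneticists and breeders working with collections of
linkage maps that share marker systems (DArT, SSR) across pedigrees.

## The method

One component map is chosen as the **seed map** (fixed backbone; by default
the map with the most markers). For each seed linkage group (LG), the
remaining homologous component LGs are merged in iteratively:

1. For every candidate component LG, count the markers shared with the
   *building* composite LG (n) and compute the Spearman rank correlation ρ
   of their positions.
2. Score each candidate with the **fit value**

       fit = |ρ| · log(n)

   which rewards order agreement and, with diminishing returns, anchor
   count. Candidates need n ≥ 3 and |ρ| ≥ 0.50 to be eligible.
3. Merge the best candidate: fit the least-squares line

       p_c = m · p_i + c

   through the anchor positions (p_c on the building LG, p_i on the
   component LG, flipped first if the component orientation is reversed) and
   place every marker *not* already on the building LG at its projected
   position. Markers already present only gain provenance.
4. Repeat — later rounds anchor on previously projected markers too — until
   no candidate is eligible.

Seed positions are never re-estimated (rigid per-LG translations only).
Before merging, component LGs are screened for gross order discordance
(|ρ| < 0.90 against every overlapping reference LG) and flagged or excluded;
afterwards, distal markers hanging ≥ 5 cM off an LG end with support from
only one component map are trimmed.

QC outputs mirror standard composite-map reporting: a per-LG summary table
(length, marker counts by type, unique loci, average interval), a
composite-vs-component marker-order correlation table, a χ² goodness-of-fit
test of whether **multicopy markers** (markers mapping to ≥ 2 LGs, putative
duplicated loci) are spread across LGs in proportion to DArT marker content,
the position-accounting identity (positions = distinct markers + extra
copies), and candidate **redundant clones** (distinct marker names
co-locating on every shared LG).

## Worked example

Simulate a three-pedigree study, build the composite, and summarize:

```
compositemap simulate --seed 7 -o data --n-maps 3 --markers-per-lg 150
compositemap build data/M1.tsv data/M2.tsv data/M3.tsv -o out --auto-exclude
compositemap summarize --composite out/composite.tsv
```

prints (abridged):

```
       length_cm  dart  ssr  gene  other  total  unique_loci  avg_interval_cm  multicopy_dart
lg
LG1       114.69    91    2     0      0     93           93             1.25               2
LG2        84.94    58    1     0      0     59           58             1.49               1
...
Total    1183.38   941   35     0      0    976          945             1.27              28

distinct markers: 962; multicopy markers: 14 at 28 positions; total positions: 976
```

Each row is one composite LG: its length in cM, marker positions by type,
distinct positions after collapsing co-located markers ("unique loci"), the
mean spacing between unique loci, and how many DArT positions belong to
multicopy markers. The closing line verifies the accounting identity
(962 distinct markers + 14 extra copies = 976 positions). `out/` also
contains the full composite map TSV (with per-marker provenance and merge
round), a MapChart-compatible export, the merge log — one row per merge
round, e.g.

```
building_lg  round  component_map  component_lg  n_common  rho       orientation  fit_value  slope
LG1          1      M1             LG1           15        0.996429  forward      1.171891   0.913997
LG1          2      M2             LG1           10        1.000000  forward      1.000000   1.024942
```

— plus the colinearity screen report, correlation table, χ² block and
redundant-marker candidates.

Real component maps are plain TSV/CSV files with columns
`linkage_group  marker  position  [type]`; `compositemap build` accepts any
number of them.

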