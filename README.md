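# meltid

High-resolution melting (HRM) curve analysis for earthworm species and COI
haplotype identification.

Earthworms are keystone soil organisms, but identifying them morphologically
is slow and often impossible for juveniles. HRM offers a cheap, sequencing-
free alternative: a short mitochondrial COI fragment is amplified with an
intercalating dye, then slowly heated while fluorescence is recorded; the
temperature at which the duplex dissociates — and the shape of the melt
transition — depends on the amplicon's sequence, so species and even
haplotypes can be told apart by their curves. `meltid` implements the full
analysis chain for an assay of this kind, aimed at soil ecologists and
molecular labs running plate-based HRM identification:

1. **Melt-curve processing** (`meltid.meltproc`) — from raw relative
   fluorescence units F(T) on a 65–95 °C / 0.1 °C ramp to melting curves
   −dF/dT, peak melting temperatures T<sub>m</sub> (parabolic sub-grid
   refinement), technical-replicate means, and *difference curves*
   d<sub>i</sub>(T) = m(T) − (−dF/dT)<sub>i</sub>(T), where m(T) is the mean
   melting curve of the reference set.
2. **Taxon assignment and genotype clustering** (`meltid.assign`) — nearest-
   reference classification with distance D(q, ℓ) = ‖q − c<sub>ℓ</sub>‖₂ on
   a 70–85 °C analysis window, explicit *unassigned* (D > τ_reject) and
   *ambiguous* (runner-up within τ_margin) outcomes, multiplex-PCR melt
   resolution of ambiguous species pairs, and average-linkage agglomerative
   clustering of difference curves into melt groups.
3. **In-silico PCR** (`meltid.insilico`) — IUPAC-degenerate primer
   expansion, 3′-anchored binding-site search on both strands, and product
   prediction for the assay's degenerate COI primers (built-in registry in
   `meltid.primers`, default pair EW_COI_F2 × EW_COI_R1, 158 bp).
4. **Haplotype analysis** (`meltid.haplo`) — primer-anchored subregion
   extraction, exact-identity haplotype collapsing, p-distance matrices and
   UPGMA trees, and concordance scoring between melt groups and sequence
   haplotypes.
5. **Synthetic data** (`meltid.synthdata`) — planted-truth sequence sets and
   melt plates from a two-state melt model (logistic helicity, linear
   baseline, Gaussian noise; T<sub>m</sub> = 81.5 + 16.6·log₁₀[Na⁺] +
   0.41·GC% − 600/N), so every stage is testable without instrument data.

## File formats

Melt tables are plain delimited text (comma or tab, auto-detected).
The canonical *wide* dialect is:

```
temperature,A1,A2
65.0,1000.0,998.2
65.1,999.1,997.5
```

A *long* dialect (`sample_id,temperature,rfu`) is also read. Sample sheets
are delimited tables with columns `sample_id,label,replicate_group,role`
(role: `reference` or `unknown`). Spreadsheet instrument exports are used by
saving the relevant sheet as CSV/TSV first. Sequences go in and out as
FASTA; trees come out as Newick.

## Worked example

```sh
meltid simulate --scenario chlorotica_haplotypes --seed 3 --out-dir fx/
meltid process --in fx/melt.csv --sheet fx/samples.csv \
               --out curves.csv --diff-out diffs.csv
meltid cluster --in diffs.csv --out groups.tsv
meltid haplotypes --in fx/seqs.fasta --table haps.tsv --tree tree.nwk
```

which prints (abridged):

```
chl01_r1        Tm=73.68
...
chl28_r1        Tm=74.81
3 groups at cut 0.4576
8 haplotypes from 28 sequences
```

The simulated panel is 28 individuals of *Allolobophora chlorotica*
carrying 8 COI haplotypes. The haplotype step recovers all 8 from the
sequences, while the melt curves cluster into only 3 groups: within a
group, haplotypes differ by GC-neutral substitutions (A↔T, G↔C), which
leave the amplicon's melting temperature unchanged — distinct sequences,
indistinguishable curves. `groups.tsv` maps each well to its melt group,
and `meltid.haplo.concordance` verifies that every haplotype falls in
exactly one group (here: group 1 = {h1}, group 2 = {h2, h3, h6, h7},
group 3 = {h4, h5, h8}).

The same toolkit classifies unknown wells against a reference library
(`meltid classify`) and predicts PCR products for any primer pair
(`meltid insilico-pcr --templates ref.fasta --fwd EW_COI_F2 --rev EW_COI_R1`).

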