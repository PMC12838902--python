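# Methods

## Scope and model

`dockcsp` checks a predicted protein–ligand pose against per-residue NMR
chemical-shift-perturbation (CSP) data. It does not predict structures or
poses (those arrive as PDB/mmCIF input) and does not touch NMR raw data
(shift tables arrive assigned); the package covers everything between:
contact classification, CSP profiling, and the consistency verdict.

## Distance-binned contact classification

Every receptor-residue ↔ ligand-heavy-atom interaction ("binding site") is
classified purely by distance *d* into contiguous half-open bins (lo, hi]:

| class | default bin | physical reading |
|---|---|---|
| `moderate_hbond` | 0 < *d* ≤ 3.3 Å | moderate hydrogen bond |
| `weak_hbond_vdw` | 3.3 < *d* ≤ 4.0 Å | weak H-bond / optimal van der Waals |
| `hydrophobic` | 4.0 < *d* ≤ 7.0 Å | hydrophobic contact |

The docking literature on the PSTD system quotes two slightly different
conventions — 2.5–3.5 / 3.5–4.0 / 4.0–6.9 Å in narrative form and
2.7–3.3 / 3.3–4.0 / 4–10 Å in table headers — which moreover disagree with
some individually printed assignments (a 2.4 Å contact listed as moderate, a
3.3 Å contact as moderate, a 4.0 Å contact as weak). The default scheme above,
with inclusive upper edges and no lower floor, is the unique contiguous
three-bin scheme consistent with *every* individually printed assignment in
the reference tables bundled with the package; both published variants ship
as presets (`SCHEMES["text"]`, `SCHEMES["table"]`) and arbitrary edges can be
supplied as a custom `BinScheme`.

Distances in (0, lo] or beyond the outer cutoff classify as `None` (dropped
with a warning in table mode). *d* ≤ 0 is an error, not a class.

### Chemistry gate

By default classification is distance-only, which is what reproduces the
reference tables. An optional strict mode (`chemistry_gate=True`) demands
donor–acceptor pairing for the moderate class, using a residue-chemistry
table for the standard amino acids (backbone amide N donor except proline,
carbonyl O acceptor, side-chain polar atoms per residue) and element rules
for unknown/ligand residues (N/O acceptor; donor confirmed by an explicit
hydrogen within 1.25 Å when hydrogens are present, otherwise
over-approximated from the element). A moderate-distance pair failing the
gate is demoted to `weak_hbond_vdw` rather than dropped, so total contact
counts are conserved between the two modes.

### Enumeration and the reduction rule

Candidate pairs within the outer cutoff are found with a k-d tree
(`scipy.spatial.cKDTree`); an all-pairs brute-force oracle in the test suite
checks exact agreement (distances to 1e-9 Å) on randomized structures.
Published tables do not define what one "binding site" is, so the pairing
rule is explicit and selectable:

* `closest` (default): for each (receptor residue, ligand heavy atom) keep
  only the closest receptor atom. One ligand atom can contact several
  residues, and one residue several ligand atoms — matching hotspot residues
  with 4–7 listed entries — but never the same ligand atom twice per residue.
* `all`: every in-range pair.
* `closest_per_residue`: one contact per receptor residue.

Hydrogens never enter distance work. Altlocs are reduced at parse time to
the highest-occupancy conformer (ties: first encountered). Contacts are
reported to 0.1 Å in human-readable output and full precision in machine
output; summaries are canonically sorted, hence permutation-invariant
bit-for-bit.

### Aggregation

`total_sites` = number of classified contacts; `mean_distance` = arithmetic
mean of all contact distances (NaN and flagged when empty);
`binding_range` = min/max contact-bearing residue; `hotspot` = residue with
the largest total count, ties broken toward the lowest sequence number and
all tied residues reported.

## CSP profiling

The combined amide CSP is √(ΔδH² + (ΔδN/α)²). The titration studies this
package targets cite prior HSQC work without printing their combination
formula, so this standard form is an explicit design choice, flagged here:
α = 5 by default (the ¹⁵N shift range is ≈5× wider than ¹H); the common
0.14-weight convention is α ≈ 7.14. α is a parameter everywhere.

`significant_range` returns the maximal contiguous residue run with
CSP ≥ `fraction_of_max` × peak that contains the peak residue; contiguity
requires consecutive sequence numbers (a missing residue breaks the run).
The default fraction 0.5 reproduces a contiguous 9-residue largest-CSP range
on the bundled plateau-shaped fixtures; it shrinks (weakly) as the fraction
rises. The all-zero profile has no peak and no range (flagged, and an error
for `significant_range`).

`rank_ligands` orders profiles by descending peak CSP. Equal peaks are
broken toward the *lower* ligand concentration — an equal perturbation
reached with less ligand implies tighter binding (both interactions assumed
in fast exchange) — then alphabetically, with explicit flags for
alphabetical ties and for comparisons where a concentration is unknown.
No K_d is fitted: concentration enters only as this tie-break and caveat.

## Consistency verdict

The docking residue set (default: exactly the contact-bearing residues, so
interior gaps count against the overlap; `residue_mode="interval"` uses the
min–max span) is compared with the significant-CSP-range residues by
Jaccard index. Verdict: `consistent` if Jaccard ≥ 0.8 *and* the docking
hotspot equals the CSP peak residue; `partial` if Jaccard ≥ 0.4; else
`inconsistent`. The 0.8/0.4 thresholds are artifact-defined stand-ins for
the qualitative "almost consistent" language of the source studies, and are
parameters. Zero docking contacts or an all-zero CSP profile short-circuit
to `inconsistent` with a reason code. Residues are matched on (sequence
number, insertion code); the chains are assumed to correspond.

## Synthetic data

### Toy complexes

`make_toy_complex` places ligand atoms at exactly prescribed distances along
unit directions from chosen atoms of a backbone-only (N, CA, C) scaffold
whose residues sit 15 Å apart along x. The scaffold is deliberately
unphysical — no side chains, no realistic stereochemistry — because the
quantity under test is geometry: the generator guarantees, by construction
checks that otherwise raise `PlacementError`, that (i) realized distances
equal prescribed ones to machine precision, (ii) no placed atom comes within
2 Å of any non-target atom, (iii) the target atom is the strict nearest
receptor atom, and (iv) every other residue is beyond the bin scheme's outer
cutoff. Under these guarantees the emitted ground-truth table is provably
the complete contact set, making profiler recovery an exact test.
Consequences for realism: toy tests validate the classification and
reduction machinery, not the chemistry of real interfaces (crowded pockets,
shared ligand atoms between adjacent residues, altlocs, waters).

### CSP fixtures

`make_csp_fixture` builds free/bound shift tables realizing a prescribed
profile: background level, a contiguous plateau (the nine-residue
elevated-range analogue), and a single peak residue (the R252 analogue),
levels expressed as fractions of the peak value. The perturbation is split
between ¹H and ¹⁵N at a random angle so the combined CSP equals the target
exactly. Noise is clipped at ±2 sd; the generator rejects
sd ≥ (peak − plateau)/4, which makes peak recovery certain, and warns when
2 sd exceeds (plateau − 0.5) × peak, beyond which the significant range is
no longer guaranteed to cover the whole plateau. Residue identities follow
the PSTD N-terminus (246 KNKLKVRTAY 255); positions past 255 are padded with
alanine and are placeholders. Real titration data differ in ways the
fixtures do not emulate: peak overlap and assignment ambiguity, exchange
broadening, non-uniform noise, and incomplete coverage (prolines, unassigned
residues).

### Bundled reference tables

The transcribed per-residue interaction tables for CMP (17 rows), LMWH
(22 rows) and LFcinB11 (23 rows) and the docking-vs-NMR summary ship under
`dockcsp/data/` with a `printed_class` column recording the class column
each distance was printed under — the default scheme reproduces every one.
`fixtures_meta.json` records the known internal discrepancies of the source
tables so no code needs to rediscover them: the LMWH totals (22 listed
distances vs printed totals 21 and 20, and an R252 count of 7 vs a printed
6), and printed mean distances (4.33, 4.23 Å) that do not equal the means of
the printed lists (4.31, 4.29 Å). Tests assert the discrepancies rather than
the irreproducible printed values; only the CMP mean (4.55 Å) is
arithmetically consistent and asserted exactly.

## Numerical and interface choices

* pLDDT categories: very_low < 50, low 50–70, high 70–90 (90 inclusive),
  very_high > 90. Only the 50 and 90 bounds are standard across the
  literature; the 70 split is conventional. pLDDT is read from the B-factor
  column with no validation beyond a warning above 100.
* mmCIF uses author (`auth_`) numbering so labels match paper-style residue
  names; no renumbering, insertion codes honored.
* PDB round-trips preserve coordinates to the format's 1e-3 Å field
  precision; atom counts exactly.
* Test problem sizes: the enumeration-vs-oracle property runs 100 randomized
  complexes up to ~500 atoms, and generator-recovery properties run 50 toy
  and 50 titration seeds; these sizes give exact set-equality checks ample
  coverage while the whole suite stays in a few seconds.

## Known limitations

Distance-only classification cannot distinguish a true hydrogen bond from a
close polar clash (the chemistry gate helps but uses no angles); π-stacking
and salt bridges are not typed; no solvent accessibility, docking-score
recomputation or binding-affinity estimation is attempted; the Jaccard
thresholds are heuristics, with no null model for range overlap.
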