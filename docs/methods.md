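# Methods

## Angular description of a nucleotide

Each residue is described by seventeen angular quantities, all computed
from full-atom coordinates with a two-argument arctangent (no quadrant
loss) under the IUPAC sign convention:

| group | angles | atom quadruples |
|---|---|---|
| backbone | α, β, γ, δ, ε, ζ | O3'(n−1)–P–O5'–C5'; P–O5'–C5'–C4'; O5'–C5'–C4'–C3'; C5'–C4'–C3'–O3'; C4'–C3'–O3'–P(n+1); C3'–O3'–P(n+1)–O5'(n+1) |
| glycosidic | χ | O4'–C1'–N1–C2 (pyrimidines), O4'–C1'–N9–C4 (purines) |
| ribose | ν0–ν4 | the five endocyclic quadruples C4'–O4'–C1'–C2', … |
| pseudo-torsion | η, θ, η′, θ′ | C4'(n−1)–P–C4'–P(n+1); P–C4'–P(n+1)–C4'(n+1); same with C1' |

The five ν angles are summarized by the pseudorotation phase

    P = atan2( (ν4 + ν1) − (ν3 + ν0),  2 ν2 (sin 36° + sin 72°) ),

normalized to [0°, 360°).  The constants place the C2'-exo-C3'-endo twist
at P = 0°; each 18° sector carries a named conformation, alternating twist
(even sectors) and envelope (odd sectors), with O4'-endo at 90° and
O4'-exo at 270°.  The two-argument arctangent matters: a plain arctangent
mishandles the whole ν2 ≤ 0 half of the wheel.  A global sign flip of all
ν shifts P by exactly 180° (mirror-image pucker).

Base classification is structural, not name-based: any residue with N9 and
C4 is a purine, one with N1 and C2 (and no N9) a pyrimidine, so modified
nucleotides with arbitrary residue codes are handled.  The glycosidic
conformation is *syn* for χ ∈ (−90°, 90°] and *anti* otherwise — the
textbook window; the literature also quotes looser descriptive ranges.

Undefined values are NaN, never exceptions: α, η, η′ at the 5' terminus;
ε, ζ, θ, θ′ at the 3' terminus; any quadruple crossing a chain break,
missing an atom, or geometrically degenerate (collinear triple).

## Structure input

PDB and PDBx/mmCIF parsing is delegated to biotite; the package then keeps
only nucleotides (identified by the C1' + O4' sugar atoms — waters, ions
and amino acids have neither), resolves alternate locations (highest
occupancy wins, ties to the lexicographically smallest altloc id) and
flags chain breaks where the O3'(i)–P(i+1) distance exceeds 2.5 Å
(≈1.6 Å covalent bond plus slack; configurable) or either atom is absent.
Author residue numbers and insertion codes are preserved for all output;
internal indices are 0-based half-open.  Unknown modified residues get a
lowercase parent letter guessed from base atoms, else `n`.

## Comparison in torsion space

The circular difference Δ(a, b) = min(|a−b|, 360° − |a−b|) ∈ [0°, 180°] is
aggregated by the Mean of Circular Quantities,
MCQ(D) = atan2(Σ sin d, Σ cos d), which stays in [0°, 180°].  The global
score pools the differences of all paired residues directly (it is not a
mean of per-residue MCQs); per-residue scores feed the severity bands
[0°,15°), [15°,30°), [30°,60°), [60°,180°] and the coverage percentages.
The default angle selection is {α, β, γ, δ, ε, ζ, χ}; ν angles and
pseudo-torsions are opt-in, and the derived phase P is never a valid MCQ
term.  Undefined angles are skipped, never imputed, and every MCQ reports
the number of pooled terms so sparse comparisons are visible.

Residues are paired by the longest common subsequence of the one-letter
sequences (dynamic programming; case-insensitive so modified residues
match via their parent letter; co-optimal tracebacks resolved
leftmost-in-target, then leftmost-in-model).

LCS-TA finds the longest run of pairing positions consecutive in *both*
chains whose pooled MCQ stays at or below a threshold (default 15°,
inclusive).  Window MCQs come from prefix sums of (sin Δ, cos Δ); a binary
search on the window length finds a feasible segment quickly.  Because
circular means are not monotone in window length — a window can satisfy
the threshold while every shorter sub-window violates it — the lengths the
binary search skipped are then verified by a descending sweep, so the
result provably equals exhaustive enumeration over all O(n²) windows.
Equal-length candidates are resolved by smaller MCQ, then leftmost
position.

## Ensemble analysis

All-pairs global MCQ values form a symmetric, zero-diagonal dissimilarity
matrix.  Three views are derived from it:

- **Classical MDS (Torgerson–Gower).**  B = −½ J (D∘D) J with
  J = I − 11ᵀ/n, eigendecomposed; coordinates are the top-2 eigenvectors
  scaled by √eigenvalue.  MCQ is angular, not Euclidean, so negative
  eigenvalues can occur and are clamped to zero.  Orientation and sign of
  the embedding are non-identifiable; tests therefore compare distance
  matrices, never raw coordinates.
- **PAM k-medoids.**  Greedy BUILD initialization followed by
  steepest-descent SWAP passes.  Single-start PAM demonstrably sticks in
  local optima on small matrices (optima reachable only by a double swap),
  so BUILD is re-seeded from every point and the best run kept — still
  deterministic, and verified equal to exhaustive medoid search on
  hundreds of random instances with n ≤ 8, k ≤ 3.  k has no default; the
  caller must choose it.
- **UPGMA dendrogram** via scipy's average linkage, exported as newick
  with ultrametric branch lengths (each leaf at depth height/2).

## Synthetic chain builder

Test fixtures are full-atom chains grown by natural-extension (NeRF)
placement from ideal bond lengths/angles and prescribed torsions, so every
prescribed α…ζ and χ is realized exactly to float precision — the
round-trip oracle for the whole angle stack.  The ribose is prescribed via
the cosine pucker model ν_j = τm·cos(P + 144°(j−2)).  A closed five-ring
with fixed bonds and angles cannot carry five independent torsions, so the
ring is solved by least squares over per-vertex radial and out-of-plane
displacements with soft bond restraints; ν residuals come out below 0.05°
(build error above 1°), bond lengths within ~0.05 Å of ideal.  The solved
ring attaches rigidly to the backbone about the shared C3'–C4' axis, a
rotation that leaves every endocyclic torsion invariant; the free spin is
fixed at a tetrahedral offset from the prescribed δ direction.  Bases are
minimal rigid fragments (N9/C4/C8 or N1/C2/C6) placed so that χ is exact.

The random-prescription generator draws torsions uniformly from
(−180°, 180°], phase from [0°, 360°) and amplitude from [35°, 45°] — the
physiological pucker-amplitude band — covering the whole torsion space
rather than the narrow distributions of real RNA.  Fixtures are therefore
geometrically self-consistent but not energetically plausible, and contain
no experimental pathologies (altloc clouds, partial residues, crystal
contacts); passing tests demonstrate the correctness of the angular
machinery, not robustness to every artifact of deposited structures, which
is instead covered by targeted parser tests.

## Numerical choices and problem sizes

- Torsions are reported in (−180°, 180°], P in [0°, 360°); CSVs use two
  decimals and blank cells for undefined values.
- Degenerate dihedrals (collinear within ~1e-9 relative) are undefined.
- Circular statistics use the Mardia definitions; the mean is undefined
  when the resultant length vanishes (< 1e-12).
- MCQ with a vanishing resultant (e.g. the two-point set {0°, 180°}) is
  reported undefined rather than an arbitrary angle.
- Verification sizes: the Δ grid is exhaustive at 1° steps (129,600
  pairs); round-trip uses 100 random 10-mers with 20 rigid motions each;
  LCS-TA is checked against exhaustive enumeration on 200 random paired
  chains of length ≤ 30; PAM against brute force on 50 random matrices
  (n ≤ 8, k ≤ 3); MDS on 20 random planar configurations (n ≤ 10).

## Known limitations

- No secondary-structure annotation from 3D; dot-bracket context, base
  pairs and stacking are out of scope.
- MCQ averages: a single bad residue inside a long well-modeled region is
  diluted; the per-residue table and LCS-TA are the local complements.
- The MDS plane distorts angular dissimilarities that violate the
  Euclidean embedding assumptions (clamped negative eigenvalues measure
  that distortion).
- The builder's ring geometry trades exact bond lengths for exact pucker
  torsions; it is a fixture generator, not a refinement tool.
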