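# Methods

## The dose-series model and its assumptions

The assay measures enzymatic hydrolysis of fucoidan by repeated FTIR
acquisition: for each enzyme dose *d* a run of spectra is recorded at a
fixed interval, and after subtraction of the buffer/substrate background the
data form a three-way tensor `X[dose, time, wavenumber]`. The package
assumes the hydrolysis signal is **trilinear with a single component**:

```
X[d, t, w] = s·dose_d · B[t] · A[w] + ε[d,t,w]
```

- `A` (spectral loading): the signed pattern of band changes. Digestion of
  fucoidan increases absorbance near 1150–1200 cm⁻¹ and 1300–1350 cm⁻¹
  (glycosidic C–O–C stretching region) and decreases it near
  1200–1250 cm⁻¹ (sulfate S=O) and 1400–1500 cm⁻¹ (carboxylate O–C–O).
- `B` (time loading): a monotone, saturating progress curve.
- `C[d] = s·dose_d` (dose score): proportional to enzyme concentration with
  slope `s` (score per µM), the quantity the activity unit is built on.
- `ε`: i.i.d. zero-mean Gaussian noise, homoscedastic across the tensor.

A single trilinear component is a strong assumption: it means the *shape*
of the spectral change and of the progress curve is dose-independent and
only its magnitude scales. That holds for a single dominant reaction
followed far from substrate depletion, and it is what makes the
one-component PARAFAC score a valid dose response.

## Synthetic data generator (`fucokit.synthetic`)

The generator's defaults state the assay's world:

| parameter | default | why |
|---|---|---|
| doses (Fe preset) | 0, 0.38, 0.86, 1.71, 3.43, 4.57 µM | the dose ladder used on *F. evanescens* fucoidans; the blank is part of the series |
| doses (Sl preset) | 0, 0.57, 1.14, 2.29, 3.43, 4.57 µM | the ladder used on *S. latissima* fucoidans |
| spectra per run | 100 at dt = 16.6 s | acquisition geometry of the instrument protocol |
| wavenumber grid | 1000–2000 cm⁻¹, step 4 cm⁻¹ (251 points) | the scanned range; the per-point resolution is not published, 4 cm⁻¹ is a typical FTIR digital resolution and a free choice here |
| band shape | Gaussian, width 20 cm⁻¹ | only band regions and signed extents are published, not lineshapes; a ~20 cm⁻¹ σ keeps the four bands resolved within their stated 50 cm⁻¹ windows |
| band amplitudes (Fe) | +2 @1175, +1 @1325, −0.5 @1225, −3 @1450 | the published signed score extents per region |
| band amplitudes (Sl) | +5 @1175, +2.5 @1325, −6 @1225, −9 @1450 | the larger changes observed on the more complex substrate |
| time loading | 1 − exp(−k·t), k = 0.002 s⁻¹ | only monotone evolution is published; this rate reaches ≈96% saturation within the 100-spectrum run, i.e. most of the progress curve is observed |
| score per µM | 0.001 (Fe), 0.0129 (Sl) | the magnitudes of the published calibration slopes |
| noise | Gaussian, sd given absolutely or as a fraction of peak signal; seeded | reproducibility requires an explicit seed |

**Scaling convention.** The spectral and time loadings are normalized to
unit Euclidean norm before the tensor is formed, so the generating dose
score `s·dose` is already on the PARAFAC dose-score scale (the fitted model
also keeps A and B at unit norm). Without this, the generator's slope and
the fitted calibration slope would differ by the factor ‖A‖·‖B‖ and the
closed-form truths used in testing (`c_unit = 0.01/s`) would not hold. Band
amplitudes therefore set the *shape* of the spectral loading; magnitude
lives in the score, mirroring the convention that Matrix C carries the
dose–response information.

What the generator does **not** emulate: instrument drift, water-vapor
lines, scattering baselines, dose-dependent spectral shapes (rank > 1
signal), heteroscedastic detector noise, or physical absorbance units. A
green test on synthetic data therefore establishes the correctness of the
estimation machinery under the stated model — not robustness to real
instrument artifacts.

## PARAFAC by alternating least squares (`fucokit.parafac`)

Standard ALS over the three mode unfoldings with Khatri–Rao products;
generic in the number of components R, used with R = 1 here.

- **Initialization**: leading singular vectors of each mode unfolding
  (`init="svd"`, deterministic, the default) or seeded random vectors for
  degeneracy checks.
- **Convergence**: relative change of the residual sum of squares
  < `tol = 1e-8`, `max_iter = 500`. The residual history is stored and is
  non-increasing by construction.
- **Indeterminacies**: per component, A and B columns are scaled to unit
  norm (magnitude into C); B is flipped so the reaction runs forward
  (`B[-1] ≥ B[0]`), then A is flipped so the dose scores trend upward
  (`C[-1] ≥ C[0]`). Each flip negates two factors, leaving the
  reconstruction unchanged. A published calibration slope's sign is thus
  treated as an orientation artifact, and the activity module uses |a|.
- **No preprocessing**: the background-subtracted tensor is decomposed
  directly; centering or scaling would destroy the through-origin linearity
  of score versus dose.
- **Degenerate inputs**: an all-zero tensor and non-finite entries are
  rejected with explicit errors.

## Activity calibration (`fucokit.activity`)

Ordinary least squares through all (dose, score) points, the zero-dose
blank included. R² is the coefficient of determination 1 − SSres/SStot
(defined as 1 for an exact two-point fit). The unit concentration is
`(threshold − b)/|a|`; a result ≤ 0 (intercept at or above the threshold)
is flagged as "activity too high to calibrate at this threshold" rather
than silently returned. `specific_activity = 1/(k_scale·c_unit)` with
`k_scale = 100` exposed as a parameter: the constant linking the unit
concentration to per-µM units is a convention of the original assay (100 is
consistent with both published activity values and plausibly reflects the
100 acquired spectra), not a derived quantity. The identity
`specific_activity · k_scale · c_unit = 1` holds exactly.

The HP-SEC calibration fits a least-squares polynomial of log10(MW) in
retention time through external standards (more standards than the degree
required). The fitted curve is checked for monotone decrease over the
standard range and a warning is raised otherwise; estimates outside the
standard range carry an `extrapolated` flag.

## Glycan structures (`fucokit.glycan`)

An oligosaccharide is a tree of pyranose residues rooted at the reducing
end; children attach through their anomeric carbon (C1) to a parent ring
position in {2, 3, 4, 6}. Fucose, being 6-deoxy, can be substituted or
glycosylated only at positions 2–4; galactose also at 6. One substituent
(O-sulfate or O-acetyl) per position; a position cannot be both linked and
substituted — `validate()` reports each violation with residue, position,
and rule.

The notation grammar is plain ASCII, written non-reducing → reducing end,
with branches in square brackets immediately after their parent residue and
substituent shorthand `2S`/`3Ac` (the `4OSO3-` form accepted as an alias).
`to_text()` emits a canonical string whose re-parse is structurally
isomorphic to the input; the backbone at each residue is the child with the
largest subtree.

Masses are computed from hard-coded standard atomic weights (average and
monoisotopic): free monosaccharide formulas (Fuc C6H12O5, Gal C6H12O6)
minus one water per glycosidic bond, plus SO3 per sulfate ester and C2H2O
per acetyl; the neutral fully-protonated form is reported. Net charge is
−1 per sulfate under full deprotonation.

The packaged shift tables store the published assignments cell-for-cell,
including the reducing-end anomer duplicates (spin systems Ea/Eb, Fa/Fb)
and the diastereotopic H6/H6′ pair of the 4,6-linked galactose stored as a
proton-shift tuple. Several rows of the octasaccharide table print the
fucose enantiomer as D although the structures are described as L
throughout; the table is stored verbatim while the OF1 structure object
uses L. No shift prediction or assignment is attempted.

## Sequence utilities (`fucokit.seqscan`)

- **Motifs**: tokens are exact residues, the `x` wildcard, or a `[..]`
  class. Every start position is tested, so overlapping hits are all
  reported; coordinates are 1-based inclusive. Exact D/H tokens are marked
  with `catalytic-D`/`catalytic-H` roles (numbered when a motif holds
  several aspartates — which of motif I's two is the nucleophile is a
  convention, so both are marked). Shipped patterns: `[RV]xxxxxDxxxxD`
  (covering the canonical arginine and the valine variant) and `DxxxGH`.
- **Alignment**: Needleman–Wunsch with linear gap scoring (defaults match
  1, mismatch 0, gap −1; no affine gaps). Traceback ties resolve
  diagonal → up → left, making alignments deterministic. Percent identity
  uses the full alignment length (gap columns included) as denominator;
  published identity values from profile-based aligners are therefore
  matched only qualitatively.
- **Neighbor joining**: canonical Q-matrix agglomeration with closed-form
  branch lengths; ties break on the lexicographically smallest label pair.
  On additive matrices the generating topology and path lengths are
  recovered exactly (verified to 1e-9). Trees serialize to Newick.

## Pipeline (`fucokit.pipeline`)

`run_pipeline(RunConfig(...))` resolves a substrate preset plus overrides
into a fully concrete generator spec (the seed is always set, default 0),
simulates, decomposes, calibrates, and returns an `ActivityReport`; with an
output directory it writes the tensor (per-dose TSV matrices + JSON axis
sidecar, 10 significant digits), the three loading matrices, and a JSON
report echoing the config digest and seed. Re-running an identical config
reproduces the report bit-for-bit. An all-zero signal raises a "no
activity detected" error instead of producing a meaningless calibration.

## Known limitations

- The rank-1 ALS objective is non-convex; the SVD initialization reliably
  reaches the dominant component for this assay's well-conditioned tensors,
  but on adversarial tensors ALS (like power iteration) can stop at a
  non-global stationary point.
- Identity percentages depend on the scoring scheme and denominator
  convention; they are not comparable bit-for-bit with profile-HMM or
  hidden-state aligners.
- The glycan model covers fucose/galactose pyranoses with sulfate/acetyl
  substituents — the chemistry of this product family — not general glycans.
- Mass calculation reports the neutral acid form; adducts and counterions
  (relevant to mass spectrometry) are out of scope.
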