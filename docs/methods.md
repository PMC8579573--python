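# Methods

## Problem and model

`amyloscan` predicts amyloidogenic regions ("hotspots") in protein
sequences. Hotspots are short segments — six residues is taken as the
minimum, and hexapeptides are the commonest experimentally characterised
unit — that promote aggregation of the whole protein into cross-β amyloid
fibrils. The predictor is a supervised classifier over hexapeptides,
applied to whole proteins through a sliding window.

Each peptide is encoded by two complementary feature blocks:

**Type 2 (series-correlation) pseudo amino acid composition.** With nine
amino-acid property scales h¹…h⁹ (z-standardized over the 20 amino
acids: subtract the mean, divide by the population standard deviation),
the lag-d correlation factor for property k is

    θ_{k,d} = (1/(L−d)) Σ_{i=1}^{L−d} h^k(R_i) · h^k(R_{i+d}),   d = 1…λ.

The encoded vector is (f₁…f₂₀, w·θ₁…w·θ_{9λ}) / (Σf + w·Σθ), where f is
the amino-acid composition block and w = 0.7 weights order information
against composition. With λ = 2 (the default) this gives 20 + 18 = 38
components. The vector always sums to 1 because the normaliser is its own
total.

**Tripeptide composition (TPC).** The 8000 overlapping 3-mer frequencies
N_i / (L−2), indexed alphabetically (AAA = 0 … YYY = 7999). TPC captures
local order and position information that composition-style features miss.

**Feature selection by binomial confidence.** Most of the 8000 tripeptides
are noise at hexapeptide scale. For tripeptide i with N_i total
occurrences, n_ij of them in class j, and q_j the class-j share of all
tripeptide tokens, the upper binomial tail

    P_ij = Σ_{k=n_ij}^{N_i} C(N_i,k) q_j^k (1−q_j)^{N_i−k}

measures how surprising the class concentration is under randomness; the
confidence level CL_i = max_j (1 − P_ij) is the ranking score. Selection
keeps either all tripeptides with CL ≥ 0.85 (default) or a top-k set; the
cutoff can be refined by cross-validating candidate ranks around the
threshold (`tune_cutoff`, maximising pooled CV accuracy, ties to the
smaller k). Never-observed tripeptides get CL = 0. Ranking ties break by
total count (descending) then alphabetically, so a selection is
byte-for-byte reproducible. The PseAAC block is never filtered.

**Classifier.** A random forest (500 trees, √d features per split, no
depth cap, fixed seed) over the concatenated PseAAC + selected-TPC
matrix. The learner sits behind a small registry keyed by name, so any
estimator with `fit`/`predict_proba` can be swapped in; the package-level
`AmyloidClassifier` is a scikit-learn estimator (get_params/clone/
pipeline compatible) whose `fit` optionally runs the selection itself.

**Region calling.** Proteins are scanned with a hexapeptide window at
step 1 (L−5 windows). A residue is called hotspot when **any** covering
window is called positive (union rule); its score is the **max** covering
window probability. Maximal runs of positive residues are the reported
regions. A peptide is called amyloidogenic when at least one of its
windows is positive. Both aggregation choices are configurable
(majority-of-covering-windows; mean score): the union rule is the most
permissive, consistent with predicted regions typically running longer
than the annotated core, and max scores preserve sharp per-residue ROC
behaviour; mean scoring smooths region boundaries at the cost of
sensitivity at region edges.

**Evaluation.** Region predictions are scored per residue: ACC, SE, SP,
the balanced accuracy Q = (SE+SP)/2, and MCC. Q is the headline metric
because hotspot residues are rare: on the 32-residue calcitonin segment
with true hotspot DFNKFH (residues 15–20), the 13-residue prediction at
residues 11–23 gets ACC 0.781 / Q 0.865, while predicting nothing at all
gets the *higher* ACC 0.813 but only Q 0.5. Multi-method comparisons use
the Friedman test on per-protein method ranks (tie-corrected mid-ranks)
with the Nemenyi post hoc critical difference CD = q_α √(k(k+1)/(6n)).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| λ (`lambda_rank`) | 2 | max correlation lag; 38-dim PseAAC with 9 scales |
| w (`weight`) | 0.7 | correlation-vs-composition weight |
| `count_mode` | `count` | f-block as raw counts (see numerical notes) |
| CL threshold | 0.85 | tripeptide selection cutoff |
| `n_trees` | 500 | forest size |
| decision threshold | 0.5 | window/peptide probability cutoff |
| folds | 10 | stratified CV folds, pooled out-of-fold metrics |

The nine default property scales are hydrophobicity, hydrophilicity,
side-chain mass, pK1 (α-COOH), pK2 (NH3), pI (25 °C) — the tables long
distributed with PseAAC tools — plus rigidity (Charton steric
parameter), flexibility (Bhaskaran–Ponnuswamy average flexibility) and
irreplaceability (negated Dayhoff relative mutability). Any table can be
substituted via a 20-row TSV (`load_scales_tsv`); standardization makes
the encoder invariant to affine rescaling of a raw table.

## Numerical choices

* **f-block as counts, not frequencies.** θ is a product of z-scores and
  can be strongly negative for anticorrelated neighbours; on random
  hexapeptides the normaliser Σf + w·Σθ goes non-positive for ~11% of
  sequences when Σf = 1 (frequency mode) but only ~5·10⁻⁵ of them when
  Σf = L = 6 (count mode). Count mode is therefore the default for a
  hexapeptide-centred tool; frequency mode remains available. The encoded
  vector sums to 1 in either mode.
* **Degenerate normaliser.** If Σf + w·Σθ ≤ 1e-12 the encoder raises
  rather than clamps: a pathological sequence/scale combination should be
  visible, not silently rescaled.
* **Binomial tails** use the survival function of the binomial
  distribution (numerically stable regularised incomplete beta), exact to
  better than 1e-12 against direct summation for N ≤ 1000.
* **MCC convention:** 0 whenever a denominator factor is 0. **SE/SP
  convention:** 0 when the corresponding class is absent.
* **Rounding in reports:** half-up to 3 decimals (0.8125 → 0.813), full
  precision retained internally.
* **Ranking and CV determinism:** explicit tie-breaks, seeded stratified
  folds, seeded forest — identical inputs and seeds give identical
  outputs, byte-for-byte for serialized feature specs.
* **Friedman statistic** is computed in the Conover form
  (k−1)·Σ(R_j − n(k+1)/2)² / (A − C), which equals the classic statistic
  with the standard tie correction and stays defined for k = 2; the
  Nemenyi q_α comes from the studentized-range distribution rather than a
  truncated lookup table.

## What the synthetic generator emulates — and what it does not

`synthetic.generate_hexapeptides` produces labeled hexapeptides in which
positives carry planted tripeptides (default VIV/IVI/VVI) with
probability `plant_rate` = 0.8 and a Val/Ile composition tilt
(`composition_bias` = 1.0 ≈ 2.3× enrichment), negatives carry NGQ/QNG/GGN
and an Asn/Gly/Gln tilt — the hydrophobic-vs-polar contrast actually
observed between amyloidogenic and non-amyloidogenic hexapeptides.
`generate_annotated_proteins` embeds positive-style hotspot hexapeptides
in negative-composition background with ≥ 6-residue gaps, so annotated
regions are unambiguous maximal runs.

This emulates the *statistical structure* the pipeline exploits
(class-biased k-mer content, composition contrast, known region
geometry), not amyloid physics: no β-sheet propensity, no gatekeeper
residues, no length- or position-dependent effects, and background
composition is i.i.d. rather than protein-like. Passing the recovery
tests therefore demonstrates that the pipeline's machinery — counting,
ranking, training, scanning, evaluation — is correct and sensitive to the
kind of signal it targets; it does not certify accuracy on real curated
amyloid data, which requires the curated training and evaluation sets.

## Problem sizes used in the test-suite recovery runs

Planted-signal runs use 200 positives + 200 negatives (10-fold CV, 500
trees) and 20 proteins of length 40–80 with two hotspots each; the null
runs use the same sizes with plant rate and bias at 0. These sizes give
stable behaviour (CV AUC ≈ 0.98 at default signal; ≈ 0.55 at null) while
the whole suite stays fast.

## Known limitations

* Default property-scale values are reasonable published tables, but the
  encoder's numeric output depends on the chosen tables; users comparing
  against other PseAAC implementations should load the exact tables they
  need.
* The union window-aggregation rule maximises sensitivity and tends to
  over-extend regions; per-residue SP is correspondingly conservative.
* Window probabilities are calibrated to the hexapeptide training
  classes. Scanning proteins whose background resembles neither class
  leaves background windows near 0.5, so the default threshold can
  over-call; raise the scan threshold or read the per-residue scores
  (ROC/AUC) when region boundaries matter.
* Selection before cross-validation (the standard usage here) leaks a
  small amount of label information into CV estimates; the null-signal
  test bounds this effect (AUC stays near 0.5).
* Hexapeptide windows cannot resolve hotspots shorter than six residues,
  and scanning refuses proteins shorter than the window.
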