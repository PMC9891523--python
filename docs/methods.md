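# Methods

## Mass bookkeeping

All masses are monoisotopic. Constants: proton 1.007276 Da, water
18.010565 Da, ammonia 17.026549 Da, CO 27.994915 Da; residue masses follow
the standard monoisotopic table. A peptide's neutral mass is the sum of its
residue masses plus one water. Cysteine is carried carbamidomethylated
throughout ("C(cam)", +57.021464 Da), matching the near-universal fixed
alkylation in bottom-up sample preparation; methionine oxidation is an
optional token ("M(ox)", +15.994915 Da) and is never auto-applied. The mass
table is overridable per token, either absolutely or as a delta on the base
residue, so non-default chemistries can be configured without code changes.

Fragment ions cover the twelve types relevant to HCD spectra: a/b/y at
charge 1 and 2, and the H2O/NH3 neutral losses of a/b/y at charge 1 only —
neutral-loss ions at charge 2 are deliberately excluded from the vocabulary.
For a peptide of length *n* each ion type contributes exactly *n*−1
fragments; `b_i` = prefix mass + proton, `y_j` = suffix mass + water +
proton, `a_i` = `b_i` − CO, and doubly charged m/z = (neutral + 2·proton)/2.
The identity `b_i + y_(n−i) = M + 2·proton` is enforced to 1 µDa in tests.

ppm matching is inclusive (`|Δ|/theoretical·1e6 ≤ tol`), with the
theoretical m/z in the denominator — the common convention; the default
tolerance is 15 ppm for both fragments and precursors. Ile and Leu carry
identical masses but remain distinct tokens in the mass layer; their
equivalence is an evaluation-layer policy.

## Digestion

Cleavage rules are Expasy-style: trypsin cuts C-terminally of K/R except
before P; LysC after K; chymotrypsin after F/W/Y/L except before P; elastase
after A/V/S/G/L/I; Glu-C after E (a D-inclusive variant is provided for
ammonium-bicarbonate buffers); pepsin after F/L/W/Y; Asp-N before D. The
rule table is user-extensible because empirical datasets routinely contain
semi-specific products that a fixed table cannot describe. Digestion is
fully specific: products span k+1 consecutive fragments for every
k ≤ `missed_cleavages` (default 2), filtered to length 6–30 and mass
≤ 4000 Da by default. The mass filter uses the carbamidomethylated Cys mass,
consistent with the rest of the package. Sequential multi-protease
digestion is modelled by composing rules (union of cleavage sites). Protein
N-terminal Met is not clipped. The digestion path is verified exactly
against an independent substring-enumeration oracle and cross-checked
against pyteomics' cleavage engine.

## Datasets and termini diversity

Datasets are collections of annotated peptides (modified sequence, charge,
precursor m/z, source enzyme, spectrum id). Uniqueness is by
modified-sequence string. Equal-size sampling (uniform, without replacement,
over unique peptides) makes diversity and recall metrics comparable across
enzymes; the sampled size defaults to the smallest enzyme set, mirroring
how a limiting dataset caps a multi-enzyme comparison. Splits are random
90/5/5 with train = floor(0.9·n) and any odd remainder record going to the
validation side; the rule is arbitrary but fixed (21492 records split as
19342/1075/1075). Every random step derives an independent substream from
the user seed, so adding a dataset never perturbs another's draw.

Termini diversity counts distinct N-terminal (`Tn`) and C-terminal (`Tc`)
residue trimers over unique *bare* sequences (modifications stripped —
trimer space is the 20-letter alphabet, so `Tn, Tc ≤ 8000`). Trimers are
well defined because datasets enforce a minimum length of 6. The diversity
factor is `DF = log10(Tn/Tc)`; base 10 is used so that a tenfold termini
imbalance reads as 1.0. A dataset restricted to one fixed C-terminal
residue has `Tc ≤ 400`, which is why fixed-terminus (monoterminal) sets are
maximally imbalanced while balanced multienzyme merges move `DF` toward 0.

## Ion recall

A series' recall for an annotated spectrum is the fraction of its *n*−1
theoretical ions with at least one peak inside the ppm tolerance. Matching
is presence-only (no intensity threshold), a peak may satisfy several
theoretical ions (no bipartite assignment — unambiguous in practice at
15 ppm), and each theoretical ion counts at most once. An empty spectrum
yields recall 0, not an error. Only singly-charged b/y ions are used by
default; charge 2 is available. The recall denominator counts all *n*−1
ions, with no exclusion for ions outside an instrument scan range — if
annotations come from an instrument with a limiting MS2 window, measured
recall will be biased low relative to this definition.

## Evaluation

Peptide-level correctness is positional identity under an equivalence
policy: Ile ≡ Leu by default (indistinguishable by mass in de novo
sequencing), modified tokens must match exactly, and near-isobars such as
Gln/Lys (0.036 Da apart) are distinct because they are resolvable at
15 ppm. An empty prediction counts as incorrect and stays in the
denominator. Recall is computed per spectrum record (test sets are spectrum
collections); grouped (per-enzyme) recalls are size-weighted consistent
with the global value. The recall-versus-maximum-length curve and the
minimum-b/y-recall grid localise failures by peptide length and spectrum
quality; grid cells with no qualifying record are reported as missing,
never as 0, and cell (0,0) is by construction identical to global recall.

## Assembly scoring

Predicted peptides (unique bare sequences, modifications stripped) are
matched as exact substrings of the target chain under Ile/Leu folding; all
occurrences count, including overlapping ones in repeat regions. Positional
frequency `f_i` is the number of matching occurrences covering position
*i*; the confident positional score is `CS_i = log2(f_i + 1)` — zero where
nothing matched, and a doubling of evidence adds one unit. Relative
coverage is the fraction of positions with `f_i > 0`. Per-domain summaries
(median `f`, median CS, coverage) require user-supplied domain intervals
(0-based half-open; no automatic variable/constant-region detection, which
would need antibody numbering schemes), and zero-`f` runs are reported as
1-based inclusive intervals — candidate blind spots such as glycan-bearing
stretches that resist digestion.

## Synthetic-data generator

The generator emulates the statistical structure of a multienzyme
experiment with recoverable parameters:

* **Proteome** — i.i.d. residues from a composition model; the default
  "vertebrate" preset uses typical proteome-wide frequencies so cleavage
  site densities are realistic; a uniform preset exists. Default 50
  proteins of 200–600 residues (pipeline demo scale).
* **Spectra** — each singly-charged b/y ion survives independently with
  probability 1 − dropout (default 0.3 per series), surviving peaks get
  uniform m/z jitter within ±5 ppm, and 10 uniform noise peaks are added
  over the fragment m/z span. Intensities are flat: the package's metrics
  are presence-based, so intensity structure would be untested decoration.
* **Predictions** — correct with probability
  `clamp(p0 · decay^(len−6) + coupling · (mean b/y recall − 0.5), 0, 1)`,
  so recall decays with length (decay < 1) and rises with fragmentation
  quality (coupling > 0). Incorrect predictions are single substitutions,
  near-isobaric within the 15 ppm precursor tolerance when feasible
  (rare with standard residues — the smallest non-Ile/Leu gap, Gln/Lys at
  0.0364 Da, fits only for peptides ≳2.4 kDa), otherwise a random
  non-Ile/Leu substitution; either way the error is invisible to precursor
  mass filtering when feasible, exercising the equivalence policy
  non-trivially.

Every stage derives its random stream from the scenario seed and the record
index, so scenarios are deterministic end to end and insensitive to
generation order.

What the generator does **not** emulate: intensity patterns, retention
time, chimeric spectra, charge ≥ 3 precursors, semi-specific or nonspecific
cleavage products, species- or protein-family-specific sequence structure,
and correlated (non-independent) ion dropout. Consequently, passing
parameter-recovery tests shows the *metrics* are implemented correctly and
are unbiased under the stated noise model — not that any predictor will
reach a particular recall on real spectra. In particular, the synthetic
single-enzyme diversity factors reproduce the qualitative
specificity-driven ordering (narrow C-terminal cutters most imbalanced)
but not the empirical magnitudes of real cell-line digests, which reflect
proteome composition and annotation-pipeline effects outside this model.

## Numerical and interface choices

* All intervals are 0-based half-open in memory and in machine-readable
  tables; human-readable report columns (per-position profiles, zero-run
  strings) are 1-based and say so.
* Output tables are tab-separated with one comment header line carrying
  the package version, seed and a 12-hex-digit configuration hash; floats
  are written at fixed precision so reruns are byte-identical.
* The MGF writer uses a fixed key order and number format; files it writes
  round-trip byte-identically through read → write. Unknown block keys are
  preserved verbatim. Malformed block nesting is reported with the line
  number.
* Degenerate inputs: peptides shorter than 2 residues have no fragments
  (error); an empty peak list gives recall 0; a dataset below the minimum
  length 6 fails trimer counting; empty prediction lists are an error for
  recall (no silent 0/0).

## Test and acceptance problem sizes

The suite validates digestion on 100 random 200-residue proteins × 7 rules
× missed cleavages 0–2 against the enumeration oracle; mass conservation on
1000 random peptides; dropout and predictor recovery on 2000-spectrum
scenarios (binomial standard error ≈ 0.01, asserted within stated bands);
and the diversity-factor ordering on a 200-protein synthetic cohort
(~8600 unique peptides per enzyme after equal-size sampling). Recall-grid
monotonicity under positive ion-recall coupling is a statement about the
correctness *probability*, so realized cell recalls — binomial estimates on
shrinking subsets — are compared between adjacent populated cells (n ≥ 30)
within three pooled binomial standard errors, plus a non-negative mean
trend along each axis; strict cell-by-cell inequality on finite samples
would reject a correct implementation with appreciable probability.

## Known limitations

* Fully-specific digestion only; no semi-specific enumeration or cleavage
  probability models.
* No deisotoping, intensity modelling or spectrum prediction; recall is
  presence-based.
* Assembly is scoring only — no sequence reconstruction from overlapping
  peptides.
* The N-side blocked-residue convention checks the residue preceding the
  cleavage site; none of the built-in N-side rules use a blocked set, so
  this only affects user-defined rules.
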