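# Methods

## Scope and data model

`protoquant` converts per-cell LC-MS feature tables into absolute in-cell
metabolite concentrations and population-level structure for plant
protoplast experiments.  The sampling unit is one protoplast, lysed in a
96-well (6 μL 0.1% formic acid + 6 μL methanol with the ajmaline internal
standard, i.e. a 12 μL extract holding the entire cell content; a 2 μL
aliquot is pooled into a QC sample).  The package operates on four
tables: a feature table (feature m/z in Da, RT in seconds, one
peak-area column per cell), cell metadata (imaged diameter in μm,
fluorescence/color flags), a compound library (name, neutral formula,
adduct, charge, expected RT, class), and calibration series.  All
interchange is plain CSV.

## Units

Amounts are pmol, calibration levels are extract concentrations in nM,
extract volumes in μL, cell volumes in pL, in-cell concentrations in mM.
The conversions are 1 nM × 1 μL = 10⁻³ pmol, 1 mM × 1 pL = 10⁻³ pmol,
and 1 pmol / 1 pL = 1 M.

## Mass and adduct arithmetic

Monoisotopic masses use a frozen most-abundant-isotope table (CODATA /
AME values, seven decimals); the test suite cross-checks it against
pyteomics.  Ion m/z is ([M] + adduct mass)/z with the adduct mass
electron-corrected (the electron matters at the 4th decimal).  ppm error
is signed, (obs − theo)/theo × 10⁶, filtered on its absolute value at
2 ppm by default.  Formula enumeration searches CHNOPS compositions with
default bounds C≤60 H≤100 N≤6 O≤20 P≤2 S≤2 and RDBE = C − H/2 + N/2 + 1
in [0, 40]; hydrogen is solved from the residual-mass window, so the
search is linear in the C×N×O×P×S grid.  Candidates are ordered by |ppm|,
then RDBE, then formula string — ties are deterministic.  Library
matching requires both |ppm| ≤ tol and |ΔRT| ≤ window (default 10 s);
isobars are resolved by the nearest in-window RT.  Serpentine, natively a
quaternary cation, is represented as the [M+H]⁺ ion of the C₂₁H₂₀N₂O₃
composition, which reproduces its observed m/z 349.15.

## Calibration and censoring

Calibration lines are weighted least squares of area against level.  The
default weighting is 1/x²: with the default series spanning six decades
(0.01–10⁴ nM), 1/x lets the top level dominate in absolute terms, the
intercept then drifts by the order of slope × a few nM, and
back-calculated low levels become meaningless.  Equal-relative (1/x²)
weighting keeps back-calculation accurate across the range; `none` and
`1/x` remain available.

The linear range is determined by an accuracy filter: a level is retained
while its mean back-calculated concentration (over replicate injections;
the simulator injects triplicates per level) is within 20% of nominal.
Offending levels are removed one at a time — worst first — with a refit
between removals, so a single aberrant level (e.g. detector saturation)
cannot drag accurate levels out with it.  Fewer than three retained
levels is a failed calibration, reported as an error.  The LOQ is the
lowest retained level; amounts implying less than the LOQ are censored:
they carry a `below_loq` flag and no number, and count as zero in
population summaries.  Amounts above the highest retained level are
reported but flagged `above_range`.  A feature with zero area in a cell
is `absent`.

Internal-standard normalization rescales each sample by
median(IS)/IS(sample).  This removes per-sample response drift (the IS
rides along with every well) but deliberately preserves the global scale;
a detector-sensitivity factor common to cells and standards cancels
through the calibration instead.  Samples with zero or missing IS are
excluded with a logged warning.  Whether the original workflow used the
IS quantitatively or only for QC is not knowable from the outside;
normalization is on by default and switchable (`normalize_is=False`).

## Cell geometry

The cell is modeled as a sphere of the single imaged diameter:
V = (π/6)d³, in pL.  Diameters span 16–45 μm, i.e. volumes 2.1–47.7 pL —
a ~22× spread, which is why concentrations rather than amounts are the
comparable quantity.  Non-sphericity and vacuole-versus-cytosol
compartmentalization are not modeled; reported concentrations are
whole-cell averages.

A solubility plausibility check is provided for monoprotic bases:
S = S₀(1 + 10^(pKa − pH)).  Quantified concentrations exceeding the cap
(e.g. ~20 mM for catharanthine at vacuolar pH 5) are flagged, never
clipped — storage above aqueous solubility (deep-eutectic phases, ion
trapping) is a finding, not an error.

## The population simulator

The generator encodes the study conditions as presets (`leaf-SA` 202
cells, `root-SA` 187, `petal-SA` / `petal-LBE` / `petal-ABH` 232): a
mixture of cell types, each with a proportion, a diameter range, and a
per-compound profile (presence probability; given presence, concentration
log-uniform between stated low/high bounds in mM — populations span
orders of magnitude, and no within-type distribution shape is observable
from the outside, so the minimal heavy-spread choice is used; draws are
independent between compounds, likewise a deliberate minimal assumption).
The leaf preset fixes idioblasts at 2.5% (midpoint of 2–3%) carrying
serpentine, catharanthine (10–300 mM), vindoline, anhydrovinblastine
(0.3–10 mM, always present in idioblasts → ~2.5% of all cells), and
vinblastine at probability 1/202 with concentration 10–80 μM so that the
*measured* maximum respects the 100 μM cap under multiplicative noise; a
30% secologanin-rich epidermis type at 50–600 mM; a 10% IPAP type with
loganic acid; a flavonoid epidermis type whose secologanin stays below
50 mM; and a low-signal mesophyll remainder.  Root has no flavonoid- or
anthocyanin-bearing type; in LBE petal the only secologanin-bearing type
always co-expresses mauritianin; petal-SA secologanin specialists draw
5–50 mM so the observed maximum stays within the reported 5–60 mM span.

The instrument model is area = response factor × amount (pmol in the
well) × mean-one log-normal noise (per-feature CV 10%) × a per-sample
response factor (CV 5%, shared with the IS — this is the error the IS
normalization removes).  Response factors vary ~3× across compounds to
mimic ionization-efficiency differences; the IS area is 5×10⁶ with 3%
pipetting CV; feature m/z and RT carry small jitters (±0.5 ppm, ±2 s) so
annotation is actually exercised.  Sub-LOQ amounts still produce signal —
censoring is a property of the analysis, not of the simulation.
Cross-contamination (default 0, per the reported minimal carry-over)
optionally adds ≤5% of a random other cell's amounts.  Calibration series
are simulated with the same response model, triplicate injections per
level over 0.01–10⁴ nM.

What the simulator does *not* emulate: chromatographic peak shapes and
integration artifacts, matrix effects and ionization suppression,
between-compound correlation within a cell, isotope patterns, missed
picking and imaging errors.  Passing tests therefore validate the
analysis chain's arithmetic, censoring logic and statistical behavior
under the stated population structure — not robustness to every failure
mode of real LC-MS data.

## Partitioning

Untargeted intensities are compared as log₁₀(area/volume + 1); the
pseudocount of 1 on the volume-normalized scale maps zero areas to zero.
Hierarchical clustering is Ward on Euclidean distances (defaults chosen,
not externally specified) with a deterministic leaf order: at each merge
the denser (larger) subtree is placed first, ties by smallest leaf index;
the tree exports to Newick.  k-means uses k = 4 by default, best of 50
seeded restarts by within-cluster dispersion, after per-feature
standardization (compound classes differ in scale by orders of
magnitude); labels are renumbered by first occurrence so repeated runs
are identical.  Marker typing applies ordered rules — serpentine →
idioblast before loganic acid → IPAP, so alkaloid-rich cells that also
contain iridoids are not mistyped — with a configurable threshold
(default 0.1 mM, roughly the LOQ-equivalent concentration of the marker
compounds in a median-volume cell) and a fallback label.

## Numerical choices and degenerate inputs

Noise factors are exactly 1 when a CV is 0, so noiseless simulation →
quantification is the identity to ~10⁻¹⁵ relative error (tested at
10⁻⁹).  An amount exactly at the LOQ is quantified (edge tolerance 10⁻⁹
relative).  Areas at or below the fitted intercept are censored, never
returned as negative amounts.  Empty populations, header-only tables and
k = 1 clustering are all defined; proportions must sum to 1 within 10⁻⁹.
All sampling flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical outputs.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` uses 20 seeded runs per tissue at the study cell
counts (202/187/232).  Fraction-type quantities are means over seeds
(sampling SD of the mean ≈ 0.7 pp for the 30% secologanin fraction);
extreme-value quantities (maxima) are taken over all cells of all runs.
These sizes make every statistic stable to well within the comparison
tolerances while keeping the whole script under a minute on one CPU.

## Known limitations

Whole-cell sphere volumes bias concentrations low for vacuole-stored
compounds; the LOQ is calibration-defined rather than signal-to-noise
defined; the compound library carries nominal retention times on a
synthetic 7-minute gradient, so real data require a library with measured
RTs; marker thresholds are concentration heuristics and misclassify cells
whose marker sits below LOQ; k-means with fixed k = 4 is a visualization
device, not a model-selection claim.
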