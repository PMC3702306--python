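# Methods

## Fragment-ion model

ETD cleaves the peptide backbone N–Cα bond. For a peptide of n residues
the package generates c ions (index i = 1..n−1, neutral mass = Σ prefix
residue masses + modification deltas + NH₃) and z• radical ions (index
j = 1..n−1, neutral mass = Σ suffix residues + mods + (H₂O − NH₃ + H) =
Σ + 1.99184 Da monoisotopic). m/z = (neutral + z·1.007276)/z. The two
series are complementary: neutral(cᵢ) + neutral(z•ₙ₋ᵢ) = peptide neutral
mass + 1.00783 Da, an identity the test suite checks to 1e-4 Da over
random peptides.

The bond N-terminal to proline does not cleave under ETD. Suppressed
ions are generated with `suppressed=True` rather than omitted: matchers
skip them, but identity verification can then *explain* the hole in an
observed series instead of penalising it.

CID b/y ladders are available behind the same interface for completeness
(`series=("b","y")`); they take no part in the ETD localization path.

z ions are modelled exclusively as z• (z+1) radicals, the dominant ETD
product. Fragment charge defaults to 1+; higher charges can be requested
up to instrument plausibility, but all worked values here are consistent
with singly charged fragments.

## Mass conventions

Three residue-mass tables are built in, selected by name:

| kind | residue masses | phospho delta | use |
|---|---|---|---|
| `monoisotopic` | lightest isotopologue | 79.96633 | default for ladders and precursors |
| `average` | abundance-weighted | 79.9799 | ion-trap data reported on average masses |
| `paper_legend` | average rounded to 2 dp | 80.00 | reproducing hand-checked legend arithmetic (S=87.08, P=97.12, T=101.11) |

Tables are plain constants (cross-checked against `pyteomics.mass` in
the tests) and can be overridden from a `key = value` text file. Note a
rounding subtlety the legend convention exists for: full-precision
average S+P sums to 184.19, while rounding each residue first gives the
quoted 184.20.

## Localization by bracket gaps

For each fragment series and charge, consecutive *matched* ions define
brackets. The observed gap is the difference of the matched peak m/z
values (charge-corrected to neutral mass), so any constant calibration
offset cancels. The residual = observed gap − unmodified span mass is
interpreted with `residual_tol` (default 1.2 Da):

- |residual| ≤ tol → unmodified span, no call;
- |residual − k·Δphos| ≤ tol (k = 1..`n_phospho`) → k phosphates on the
  span's S/T/Y residues: one acceptor → `localized`, several →
  `ambiguous`, none → `none` with a diagnostic;

The ladder is additionally anchored at its termini: a virtual index-0
fragment of known constant mass (NH₃ for c, the z• constant for z•) and,
when the precursor mass is available, a virtual full-length fragment.
Without these anchors a phosphate outside the first/last matched ion
shifts every observed ion equally and cancels out of all pairwise
differences — terminal sites would be invisible to a purely pairwise
procedure. Interior gaps remain pure peak differences.

Per spectrum, calls from independent brackets (e.g. the c and the z•
series) are combined by intersecting their candidate sets; intersection
can resolve a single-series ambiguity. Evidence across spectra is only
counted (`aggregate_sites`), never converted into a probability: the
package deliberately offers no Ascore/phosphoRS-style scoring.

`verify_identity` accepts a peptide when at least `min_series_count`
ions of one series match (default 7) and every interior hole in the
ladder is either suppressed (pre-proline) or sits inside a bracket whose
residual is mass-consistent (≈0 or ≈k·Δphos).

## Default parameters

| parameter | default | rationale |
|---|---|---|
| missed cleavages | 2 | conventional tryptic search space |
| precursor tolerance | ±2.5 Da | ion-trap survey-scan accuracy |
| product tolerance | ±0.7 Da | ion-trap MS/MS accuracy |
| residual tolerance | ±1.2 Da | a bracket residual is a difference of two peaks, so its error is roughly √2 × the single-peak error; ±0.7 would reject residuals of 80.9/79.8 that plainly indicate a phosphate on such data |
| n_phospho | 1 | mono-phosphorylated precursors; higher values test residuals against k·Δphos |
| fragment series / charge | c and z•, 1+ | ETD products; worked values consistent with 1+ |

### The bundled example and its 1.3 Da matching tolerance

The two bundled Fra-2 spectra reproduce a published worked example. The
four experimentally printed fragment values straddle mass conventions:
one spectrum's c13/c15 (1269.7/1534.8) track *average*-mass theory
(c15 sits 1.23 Da above monoisotopic), the other's c13/c16
(1269.6/1634.7) track *monoisotopic* theory within 0.1 Da. Matching both
spectra against one (monoisotopic) ladder therefore uses a 1.3 Da
product tolerance — a calibration allowance for this particular
ion-trap data, not a new default. Localization arithmetic for the
example uses the `paper_legend` table, which is the convention the
hand calculation was done in; the resulting residuals (80.90 and 79.79
vs Δ = 80) are insensitive to that choice — monoisotopic span masses
give 81.02 and 79.97 and the same calls.

In the example MGF only those four peak m/z values are experimental;
the remaining series peaks are synthetic, computed from fragment theory
consistent with each spectrum's apparent calibration and rounded to
0.1 m/z. The carrier protein in the FASTA is synthetic as well (no
construct sequence is publicly deposited): a repeat scaffold with the
real 20-mer grafted at its C terminus behind a lysine so that digestion
yields it at the documented coordinates 307–326 (peptide position 14 =
S320). The historically printed span label "317–326" covers 10
coordinates for 20 residues and is internally inconsistent; this
package adopts the site-label-consistent mapping and does not renumber
user data.

## Synthetic spectra and what the benchmark shows

`simulate_spectrum` emits the non-suppressed 1+ c/z• ladder of a
phosphopeptide with three imperfections: i.i.d. peak dropout
(probability `dropout_prob`), additive uniform noise peaks over the
scan range (default 300–1300 m/z), and Gaussian m/z jitter
(`mz_jitter_sd`). Each spectrum draws from a private RNG stream keyed by
(seed, peptide, config), so individual fixtures are reproducible and
whole experiments are deterministic given one seed. Intensities are
uninformative by default (`uniform`); a `rank_decay` model exists only
to exercise intensity plumbing.

`recovery_experiment` samples random peptides (uniform residue usage,
length 10–25 by default, at least one S/T/Y, optional injection of the
S-P-T motif that makes single-series evidence ambiguous), plants one
phosphate, simulates, and re-analyzes each spectrum against all
phosphoforms of the base sequence. Reported fractions: planted site
recovered as the unique localized call, contained in an ambiguous call,
or neither. Default problem size is 200 peptides per configuration,
which resolves accuracy differences of ~5 points and runs in seconds.

What passing these benchmarks does **not** show about real data: the
generator has uniform residue composition (real tryptic peptides end in
K/R and have biased composition), no neutral losses (−98 Da phospho loss
is prominent in CID and present in ETD), no isotope envelopes or charge
states above 1+ for fragments, and noise that is uniform rather than
structured. The benchmark measures the localization logic, not
instrument realism.

## Numerical choices and degenerate inputs

- Matching is deterministic: within one series, ions are processed by
  ascending index, each taking the nearest unused peak within tolerance;
  exact distance ties go to the lower m/z peak; a peak may be reused
  across series but not within one.
- Competing phosphoforms are ranked by matched-ion count, then total
  |error|, then modification position (ascending) — ties are resolved
  reproducibly.
- Empty peak lists match zero ions (not an error); an empty MGF yields
  an empty report with exit status 0; a precursor with no digest
  candidate within tolerance yields a `none` row.
- Peptides of length 1 cannot be fragmented; phosphoform enumeration of
  n sites on fewer than n acceptors returns an empty list.
- Reports (TSV/JSON) are byte-reproducible across reruns; timestamps
  appear only in the run log.

## Known limitations

- No probabilistic site scores or FDR control; the output is evidence
  counting by design.
- No de-isotoping, deconvolution, neutral-loss or internal-fragment
  handling; peak lists are assumed centroided and singly charged in the
  fragment dimension unless configured otherwise.
- Semi-tryptic and non-tryptic peptides are not generated by digestion;
  only trypsin is implemented.
- Intensity information is ignored by the matcher.
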