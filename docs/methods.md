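# Methods

## The markers

The pipeline quantifies tissue microstructure from diffusion-weighted
signals at two nonzero "key" b-values, Lb = 250 and Hb = 1750 s/mm²
(units: b in s/mm², diffusivities in mm²/s throughout).  Skipping b = 0
suppresses IVIM perfusion contamination at the low shell, and b = 1750
reaches the non-Gaussian (hindrance-sensitive) regime.

**Shifted ADC.** From the direction-averaged signals S(Lb), S(Hb):

    sADC = ln(S(Lb) / S(Hb)) / (Hb − Lb)            [mm²/s]

The common scale cancels in the log-ratio, so raw or b0-normalized signals
give identical values.

**Signature index.** A library holds two reference signal pairs at
(Lb, Hb): signature B = generic gray-matter-like mouse brain tissue
(0.855, 0.317) and signature A = the same tissue after a moderate increase
in diffusion hindrance (0.858, 0.370).  The intermediate reference is
S_N(b) = [S_A(b) + S_B(b)] / 2 per shell (the "mean" rule; the rule is a
named, replaceable component of the library).  With relative distances
dS_X(b) = [S_X(b) − S_N(b)] / S_N(b) and spans ΔX = dS_X(Hb) − dS_X(Lb),
a voxel signal V scores

    SI(V)  = max(ΔV/ΔA, 0) − max(ΔV/ΔB, 0)
    Sindex = (SI + 1)·25 + 25

so V = A → 75, V = B → 25, V = S_N → 50.  ΔA > 0 > ΔB, hence exactly one
max-term is active and SI is the signed position along the B↔A axis.  SI is
**not clamped**: values outside [25, 75] extrapolate along the signature
axis and are meaningful at map level (a display clamp is available for
rendering only).  With the symmetric mean rule SI is affine in the signal
pair; replacing the rule breaks that symmetry, which is why the library
recomputes ΔA, ΔB at construction and refuses degenerate (zero-span)
libraries.

**Kurtosis representation.**  Signatures and synthetic tissue use
S(b)/S0 = exp(−bD + (bD)²K/6) with diffusivity D and excess kurtosis K.
Over exactly two shells this is closed-form invertible: with
y(b) = −ln S(b), the pair (y(Lb), y(Hb)) is linear in (D, KD²/6).
`fit_two_point` implements that inversion; the test suite cross-checks it
against an independent brute-force grid search.  Parameter validity is
D > 0, K > −3, and K < 3/(b_max·D) so the signal is strictly decreasing up
to the highest shell used; `validate_against` enforces the latter at every
construction site.

## Processing chain

1. **Shell maps.** Per scan: mean of the b≈0 volumes (s0), mean of the six
   direction volumes per shell (raw), and raw/s0 (normalized).  Averaging
   raw volumes first and then dividing by s0 equals per-direction
   normalization followed by averaging (arithmetic means) and is more
   robust at low signal.  Voxels with s0 ≤ 1e-12 (configurable absolute
   floor) are masked, never raised on.
2. **Stability filter.** Per shell (b0, Lb, Hb), each scan's **raw** map is
   smoothed with an isotropic Gaussian (FWHM 1 voxel by default,
   configurable) and the temporal CV = sd/mean (in %, sd with ddof = 1)
   is computed across the session's 18 scans.  A voxel is flagged iff
   CV > threshold (default 4%, strict inequality) in any shell; a
   non-positive temporal mean flags the voxel as degenerate.  Raw rather
   than normalized maps are used because scan-level instabilities (motion,
   drift) scale all volumes of a scan together and cancel exactly under b0
   normalization — the normalized signal of an unstable scan can look
   perfectly stable.  The FWHM-1 default keeps the kernel small enough
   that a single unstable voxel retains ≈0.69 of its temporal modulation
   (a 10% modulation → ≈5.5% CV, flagged with >3σ margin against the CV
   estimator noise of an 18-sample session) while still suppressing
   noise-driven CV on the noisiest shell (raw Hb ≈ 3.2% → ≈2.3% at SNR 40)
   far below the threshold; a FWHM-2 kernel would leave an isolated voxel
   with only 0.10 of its modulation and make single-voxel instabilities
   undetectable in principle.
3. **Discard rule.** The temporal CV is a session-level statistic, so the
   discard unit is the whole subject session: any flagged voxel inside an
   analysis ROI removes the subject (flags confined to background are
   ignored).  Per-scan discard is deliberately not the default; the
   filter cannot attribute instability to individual scans.
4. **ROI markers.** ROI means of the normalized shell signals are taken
   first over valid voxels, then the markers are evaluated on the means
   ("average signals, then compute") — the log in sADC makes this differ
   from averaging voxelwise markers.  The mean-of-markers variant exists
   only as a diagnostic.
5. **Windows and time course.** Pre = first 6 scans (all pre-injection),
   post = the final 6 scans of the session; selection is order-based on
   scan index, never timestamp-interpolated.  The time course averages
   consecutive scan triples (six points at 15-minute resolution, stamped
   at triple centers: −25, −10, +5, +20, +35, +50 min for the default
   timing).  Before group averaging and per-time-point testing, a
   single-pass z-score filter excludes values with |z| > 3 against the
   group mean/SD at that time point (candidate included, no re-iteration;
   zero SD → no exclusion; fewer than 3 subjects → filter skipped).  The
   filter applies to time-course points only; window means use all
   non-discarded scans.
6. **Statistics.** Paired two-sided t-tests pre vs post per group, ROI and
   marker; Welch (unequal-variance) two-sample tests between groups for
   the pre and the post window means, Holm-corrected within each marker's
   comparison family (pre/post × ROIs); per-time-point Welch tests,
   uncorrected.  Holm was chosen over Bonferroni as uniformly more
   powerful without independence assumptions; the method name is recorded
   in the report and configurable.  Degenerate inputs (single subject,
   zero variance) yield NaN p-values rather than exceptions, and corrected
   p ≥ raw p always.

## The phantom

The generator exists so every stage is testable without any download, and
its defaults are the study conditions:

- grid 32×32×8 (full cohorts simulate in seconds at this size; the
  acquisition-matched matrix would add nothing to ROI-level claims),
- scheme 1×b0 + 6×250 + 6×1750 s/mm², six standard gradient directions,
- 18 serial scans, 5 minutes apart, injection after scan 6,
- two groups of 16 subjects (vehicle / treated),
- five ROIs with voxel counts strictly ordered DG < CA3 < hippocampus <
  striatum < cortex (the anatomical ordering; CA3 and DG are nested inside
  the hippocampus, and the hippocampus ROI includes them),
- per-ROI baseline kurtosis parameters equal to the two-point fit of
  signature B (D ≈ 6.22e-4 mm²/s, K ≈ −0.31) plus small per-ROI offsets so
  maps show regional baseline contrast; unlabeled voxels are a uniform
  tissue bath with the unmodified signature-B parameters, so a phantom has
  no temporal structure other than what is injected deliberately,
- effect: a per-ROI shift of (D, K) along the negated B→A signature
  direction (a hindrance decrease), 0 before injection, linear ramp over
  the first 3 post-injection scans, then plateau.  The cortical plateau is
  calibrated at run time by a bracketed 1-D root search so the noiseless
  cortical ROI Sindex change is −9.0% (tolerance 0.1 percentage points);
  the hippocampus (with CA3 and DG) gets 1.3× the cortical shift and the
  striatum none.  The search domain is |α| ≤ 1 signature distance — beyond
  the library span the linear signature direction has no meaning — so
  absurd targets (e.g. −200%) fail loudly,
- noise: Rician, i.e. the magnitude of the noiseless signal plus complex
  Gaussian noise with per-channel SD = s0_ref/SNR, SNR 40 at b0 (Gaussian
  available for analytic checks; SNR = None gives noiseless data).  At
  SNR 40 the Rician floor biases the b0 mean by <0.1% (verified in tests),
- instabilities: optional per-voxel sinusoidal multiplicative modulation
  (period 6 scans) applied to **all** volumes of a scan — a scan-level
  intensity instability, which is why the QC runs on raw shell maps,
- seeding: one mandatory master seed; per-subject generators are spawned
  from it (`SeedSequence.spawn`), so cohorts are bit-reproducible and
  subjects independent.

Signals are isotropic by design (identical across the six directions): the
pipeline consumes only direction-averaged signals and no anisotropy claim
is made, so the phantom stays honest about what is tested.

### What the phantom does *not* emulate

Real anatomy and partial-volume mixing, EPI distortion, motion and
eddy-current artifacts, perfusion (IVIM) contributions, direction-dependent
diffusion, and between-subject biological variability beyond noise.
Passing tests therefore demonstrate that the *computational chain* is
correct and well-calibrated at the study's geometry, noise level and effect
size — not that the markers behave identically on real scanner data, where
upstream registration, bias-field correction and denoising (out of scope
here) matter.

## Numerical choices and degenerate inputs

- Shell assignment by absolute distance to the three expected shell
  centers within a tolerance (default 25 s/mm²); ambiguous or orphan
  b-values are rejected at read time.
- All validation errors are typed (`ValidationError` subclasses); readers
  never silently coerce.
- Marker maps and phantom volumes are written as float64 NIfTI-1, result
  tables as full-precision CSV, so write-then-read is the identity and
  repeated runs with one seed are byte-identical.
- Empty ROIs raise; fully masked scans warn and propagate masks; paired
  tests with n < 2 or zero variance report NaN.
- The stability threshold boundary is exclusive (CV exactly at threshold
  is not flagged).

## Expected behaviour at the default conditions

With 16 subjects per group, ROI-mean signal noise is far below the
calibrated effect, so the paired pre/post tests in the treated group's
cortex and hippocampus (Sindex down, sADC up) are significant in
essentially every seeded replicate, while striatum and vehicle cells are
null.  Null cells still produce p < 0.05 at roughly the nominal 5% rate —
the two markers are computed from the same signals, so such a chance event
usually appears in both markers of one ROI at once.  The acceptance tests
therefore check power per effect cell (≥90% of replicates) and the pooled
false-positive rate over all null cells and replicates (≤10%), which is
the property a correctly calibrated pipeline can actually guarantee.

## Known limitations

- The two-point kurtosis inversion is exact only under the kurtosis signal
  representation; it is a parameterization device, not a full DKI fit (no
  tensors, no direction dependence).
- The signature library ships with the printed two-signature values; the
  (Δd, Δk) used to synthesize signature A from B is recoverable from the
  fits but the library defaults come from the signal values themselves.
- Whole-session discard is conservative: one unstable voxel inside an ROI
  costs a subject.  At cohort scale the ~0.01% per-voxel false-flag rate
  still discards an occasional clean subject; the filtered manifest and
  discard log make this auditable.
- Per-time-point tests are uncorrected by design; with 36 tests per cohort
  some nominal-level significance is expected under the null.
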