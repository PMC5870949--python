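# Methods

This note documents the models, estimators, defaults and design choices
behind `navdup`, and what its synthetic-data tests do and do not show
about real data.

## Parsimony mapping on a duplication trio

Two paralogs plus one distant outgroup ortholog admit a single unrooted
tree with one internal node, so minimum-mutation parsimony reduces to a
per-column rule: identical columns carry no event; a column where two
sequences share a residue and the third differs carries one substitution
on the branch of the differing sequence; a column where all three differ
carries one substitution on each branch (the minimum possible). The
all-different rule inflates the total count at such columns, but the
inflation applies to all branches and cancels from the relative-density
ratio downstream.

Indels: a maximal run of contiguous gap columns charged to one branch is
one mutational event at the run's first column (`indel_mode="per_run"`,
the default — one insertion/deletion is one mutation); `per_column` mode
counts every gap column and is retained for sensitivity analysis. Columns
with two gapped sequences charge the residue-bearing branch (a
lineage-specific insertion). Columns containing `X` in any sequence are
skipped and logged: parsimony is undefined on missing states. A column
with exactly one gap contributes only its indel event; a residue
difference between the two non-gapped sequences at such a column is
parsimony-ambiguous between two branches and is deliberately not called.

## Substitution-density hotspot scan

For branch *b* with events at columns p_1..p_{n_b}, the weighted density
at column x is

    d_b(x) = (1 / n_total) * sum_i phi_h(x − p_i),

a Gaussian kernel density (sd *h* = 15 residues, the bandwidth of the
smooth profiles this analysis is built around) normalized to unit mass
and weighted by the branch's event share w_b = n_b/n_total. Events are
integer columns, so the density is computed exactly by discrete
convolution of the per-column counts with the kernel sampled at integer
offsets and truncated at 6 sd (tail mass < 1e-9); no boundary correction
is applied, so mass is lost at the alignment edges, as in the default
kernel estimator. The relative density is

    R_b(x) = d_b(x) / max(sum_{b'≠b} d_{b'}(x), eps),

with eps = 1e-8 events/residue applied identically in observed and null
computations.

The null distribution re-places n_b events per branch uniformly at random
with replacement, recomputes R with the same kernel, truncation and
floor, and records the per-simulation maximum over columns; the per-branch
threshold is the empirical 99th percentile of those maxima (default
N_sim = 10,000). Using the maximum makes the threshold familywise: a
branch with uniformly placed events exceeds it *anywhere* along the
alignment in ~1% of datasets. This calibration is per branch — the union
over the three branches necessarily runs near 3%. A pointwise
(per-position) null is available behind `statistic="pointwise"` for
sensitivity analysis; it has far more power for localized windows but its
anywhere-exceedance rate under the null is tens of percent, so called
regions then carry per-position, not familywise, error control.

The observed event maps and the null use the same placement primitive and
the same density code path, which is what makes the test valid by
construction.

**Power is driven by the denominator, not the numerator.** The
per-simulation maximum of R is heavy-tailed: its large values come from
stretches where the *other* branches happen to have no events nearby
(the denominator collapses toward the floor). Consequently a window
carrying a 10x elevated event rate on one branch against uniform
backgrounds on the others (the window then holds ~10% of that branch's
events) reaches peak R ≈ 1.8, while the familywise threshold is >= 2.2
under every event-budget combination we measured — such a window is
essentially undetectable (power ~0–20%), and the corresponding acceptance
test records this honestly as a failure. Detectable hotspots, including
the kind this scan exists to find, pair a substitution burst on one branch
with *conservation* of the same region in the other lineages: the
denominator is then locally tiny and R rises orders of magnitude above
threshold. The pipeline's positive-control fixtures are constructed with
that geometry.

## GY94 branch models and the selection LRT

Codon substitution rates over the 61 sense codons follow Goldman–Yang:
zero for multi-nucleotide changes, pi_d for synonymous transversions,
kappa·pi_d for synonymous transitions, multiplied by omega = dN/dS when
the change is nonsynonymous. Equilibrium frequencies come from F3X4:
empirical nucleotide frequencies at the three codon positions multiplied
per codon, stops removed, renormalized. Each omega class's matrix is
rescaled so branch lengths are expected substitutions per codon under
that class.

Likelihoods use Felsenstein pruning over unique site patterns with
per-node rescaling; gap or ambiguous codons are missing data (partial
likelihood 1 over all states; a `drop_gap_columns` switch removes gapped
columns instead). The transition matrix exp(Qt) is computed from the
eigendecomposition of Q in the pi^(1/2)-symmetrized basis — exact for
this reversible model, and cached per (kappa, omega) so that the
finite-difference branch-length derivatives of the optimizer reuse it.

Fitting maximizes lnL jointly over log-kappa, log-omega per class and
log branch lengths with bounded L-BFGS-B from `n_starts` (default 3)
jittered starting points; branch lengths are re-estimated under each
model by default (`fix_branch_lengths=True` keeps the tree's). The
one-ratio and two-ratio models are nested; 2ΔL is compared against
χ²(1). Profile-likelihood intervals for the foreground omega invert that
test: omega_0 lies in the 95% interval iff the refit with the foreground
omega pinned at omega_0 loses less than χ²(1, 0.95)/2 = 1.92 log units.

Calibration, measured by the test suite: under one-ratio simulation
(500 codons, 3 taxa) the LRT rejects at the χ²(1) 5% critical value in
5.3% of 600 replicates; under two-ratio simulation at 1,800 codons with
background omega 0.090 and foreground 1.58 (foreground branch 0.15
substitutions/codon) the profile interval covers the generating omega in
>= 90% of replicates and the LRT rejects at alpha = 0.01 in 100%.

## Voltage-clamp analysis

All estimators operate on piecewise-constant voltage protocols with the
sampled current (default acquisition 50 kHz, holding −120 mV):

- **Leak subtraction.** Steady-state currents from protocol segments at
  or below −105 mV are fit with a line I = g·V + b and g·V(t) + b is
  subtracted sample-wise. The window is deliberately kept within ~15 mV
  of holding: the far tail of a sodium-channel activation curve
  (V½ = −40 mV, k = 7 mV) still passes ~0.1–0.2% of maximal current at
  −90/−95 mV, and admitting those steps tilts the leak line enough to
  bias small persistent-current percentages by several tenths of a
  percentage point. Families without two distinct subthreshold voltages
  (steady-state inactivation, recovery) take the leak parameters fitted
  on the step family of the same cell.
- **Persistent current.** %I_NAP = 100 × (mean current over the last
  0.5 ms of the 30-ms pulse) / (transient peak), per sweep; the peak is
  the extremum of the 10-kHz low-pass-filtered trace (mirroring
  acquisition filtering) and sweeps whose peak is below 3 baseline
  standard deviations are skipped.
- **Gating curves.** Activation: G(V) = I_peak/(V − E_rev) normalized and
  fit with a pedestal-free Boltzmann rising in V. Steady-state
  inactivation: normalized test-pulse peaks vs conditioning voltage fit
  with a + (1 − a)/(1 + exp((V − V½)/k)); the pedestal *a* is the
  non-inactivating fraction. Recovery: test/conditioning peak ratio per
  interval.

## Synthetic data

- **Codon trios** evolve from a root drawn from the equilibrium
  frequencies as an explicit per-site jump process, so every realized
  substitution (branch, column, syn/nonsyn) lands in a truth ledger —
  parsimony mapping is audited against realized events, not just
  endpoints. Hotspot windows multiply the nonsynonymous rate inside
  1-based codon intervals on one branch. Multi-taxon alignments for the
  selection tests use endpoint sampling with exp(Qt). Default codon
  frequencies are the uniform-nucleotide F3X4 (pi_c = 1/61).
- **Event maps** place events per branch uniformly (the exact null
  placement primitive) or with window multipliers, for scan calibration
  and power studies.
- **Traces** follow Hodgkin–Huxley-style kinetics: activation gate m
  relaxing toward m_inf(V) with tau_m = 0.1 ms (m_inf cubed is exactly
  the target activation Boltzmann, so fitted G–V parameters are
  comparable to inputs), inactivation gate h with a three-zone
  voltage-dependent time constant (tau_h = 3 ms depolarized, tau_rec =
  2 ms at <= −110 mV, tau_slow = 100 ms between — the slow middle zone
  keeps the 1-ms −100 mV gap step of the SSI protocol from spuriously
  recovering channels, limiting availability drift to ~1%). Channel
  current is g_max·m³·[(1 − p)·h + p]·(V − E_rev) with persistent
  fraction p, plus ohmic leak and additive Gaussian noise. Step families
  span −115..+35 mV so the leak fit has several channel-free voltages.
- **Expression tables** are log-normal around specified gene medians, so
  zero dispersion reproduces the means exactly.

All generators are bit-reproducible from (spec, seed).

**What recovery means for the trace estimators.** The quantities the
analysis reports are properties of the recording, not bare generator
dials. With tau_m = 0.1 ms and tau_h = 3 ms the transient peak is
attenuated to ~0.90 of its instantaneous envelope, so the true late/peak
ratio of a noiseless trace with persistent fraction p = 0.06 is ~6.6%,
and the true SSI pedestal for p = 0.05 is ~0.065 (attenuation plus gap
drift). Accuracy tests therefore compare the estimator against the
noiseless, leak-free family's own value — the estimator is unbiased to
<0.3 percentage points (%I_NAP) and ~0.005 (pedestal) at the default
signal-to-noise ratio — while separately asserting that the noiseless
truth sits close to the nominal parameter.

**What the synthetic tests do not show.** The trace generator has no
capacitance transients, series-resistance error, slow drift or seal
degradation; real oocyte recordings have all four, so passing round
trips bound estimator error, not recording error. The codon simulators
have no alignment error, no indel-driven misalignment, and (by default)
no codon-usage skew; the hotspot generator has no spatial correlation of
substitutions beyond the planted windows and no site-specific
constraint, so the scan's calibration on these inputs does not certify
calibration under real heterogeneous constraint.

## Expression and qPCR utilities

Isoform abundances are summed within transfrags; multiple transfrags per
gene are combined by mean (default) or max — both summaries are exposed
because they give very similar relative patterns on well-assembled
transcriptomes and neither is canonical. TPM and FPKM are relative
units, so cross-sample comparisons use shares of summed sodium-channel
expression within each tissue (invariant to common rescaling);
cross-unit absolute comparisons are refused. qPCR fold changes use
2^-ΔΔCq with efficiency fixed at 2.0 (100% doubling); a per-run
efficiency override exists, but efficiency *estimation* is out of scope.

## Problem sizes in the test suite

The shipped suite runs on one CPU in ~6 minutes: hotspot calibration on
1,000 trios (1,800 columns; 100/60/60 events; 1,000 null simulations per
trio — a scaled-down null; the analysis default remains 10,000), window
power on 200 trios, selection recovery on 50 replicates of 1,800 codons,
LRT null calibration on 500 replicates of 500 codons, and 100-replicate
Boltzmann recovery sweeps. `scripts/acceptance.py` recomputes the same
quantities at similar scale in ~3 minutes.

## Known limitations

- The hotspot scan evaluates densities on shared alignment columns (the
  cross-branch ratio requires a common coordinate system); per-protein
  coordinates would differ wherever the alignment is gapped.
- The familywise max-statistic threshold is conservative for localized
  signals against uniform backgrounds (see above); use the pointwise
  mode when screening for candidates rather than testing.
- Two-ratio fits assign a single foreground class; site-model and
  branch-site-model heterogeneity is out of scope.
- Branch lengths and kappa are estimated per model without standard
  errors; uncertainty is exposed only for the foreground omega (profile
  likelihood).
- The leak model is a single ohmic line; P/n subtraction and capacitance
  correction are not implemented.
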