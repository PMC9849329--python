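# Methods

## Scope and modeling assumptions

The package models splicing commitment of a single cassette exon flanked by
two constitutive exons, under exon definition: an intron can only be removed
once both flanking exons are fully synthesized and recognized. Commitment
reactions are irreversible and first order, so PSI computed from a single
synchronized cohort (precursor mass 1 at t = 0) equals the steady-state
isoform ratio of a continuously transcribed gene with equal isoform
turnover. Not modeled: reversible spliceosome binding, intron-definition
(64-state) recognition, recursive splicing, RNA secondary structure,
long-range RBP looping, and NMD.

## Delay commitment model

States mRNA, mRNA_inh, Incl, Skip with rates ki (inclusion, always active),
kesc (escape into the RBP-inhibited state, active only in the deposition
window [tau_inh1, tau_inh2]) and ks (skipping, active after tau, from both
mRNA and mRNA_inh). Delays derive from a four-segment geometry (k, e, m, n
length units over tr_len nucleotides): tau_inh1 = tr_len/(l vpol) k,
tau_inh2 = tr_len/(l vpol)(k+e), tau = tr_len/(l vpol)(k+e+m). The
phase-wise active-rate table (phase 1 {ki}; 2 {ki, kesc}; 3 {ki};
4 {ki, ks}) is a package reconstruction of the window logic and is
configurable (`PhaseTable`).

Two solvers: phased LSODA integration (rtol 1e-8, atol 1e-10; integration
error is orders of magnitude below every tolerance used) and the exact
probability recursion E_i = (sum of active rates) dt_i,
p_react,i = p_rest,i-1 (1 - e^-E_i), with the inclusion share ki/(sum).
Phase 4 is treated as genuinely infinite (p_react = p_rest), not as a large
finite time. Edge case: with ks = 0 and kesc > 0 the escaped mass never
commits; it is excluded from the PSI denominator (PSI = incl/(incl+skip)
over committed mass only). The default integration horizon is t = 1e4 s
with a residual check; tests needing 1e-6 agreement with the closed form
extend t_end to tau + 60/min(ki+ks, ks) so the slowly draining mRNA_inh
pool finishes.

## Multistep model

P-chain of l steps (escape window steps k+1..k+e feeding a parallel
E-chain; skipping from the last n states of both chains; terminal states
exit only by splicing), kelong = vpol l / tr_len. The escape-window
placement for general (k, e, m, n) follows the printed 8-step instance.
Backends: adaptive ODE (default, parity with the delay model) and matrix
exponential (exact, used for velocity scans). Arrival at step j is Erlang
with mean (j/l) tr_len/vpol, matching the hard delays in expectation;
convergence to the delay model is monotone in l (tested over l = 8..160).

## Mechanistic exon-definition model

19 species: 8 spliceosome-binding patterns P000..P111, their RBP-bound
copies, and the fates ret/Incl/Skip. Splicing kspli from P111 (inclusion)
and kspls from P101 (skipping), both defaulting to the same value
(k_spl = 0.2 1/s); retention is a single lumped first-order exit (kret)
from every unspliced state, active only after transcription ends. The RBP
binds irreversibly (rbp_br) in a window [rbp_pos/vpol,
(rbp_pos+pol_range)/vpol]: the deposition reach is taken downstream of the
motif (the open geometric question; upstream or centered windows can be
emulated by shifting rbp_pos). Exon-definition rates switch on at
exon_end/vpol. Each phase between sorted delay events is linear and
time-invariant; the default path integrates it with LSODA and an exact
matrix-exponential propagation of the same phase matrices serves as the
test oracle (agreement to 1e-8).

RBP modulation: kx_inh = kx (1 - f(d5SS)) (1 - f(d3SS)) with
f(x) = 1/((x/range)^p + 1) evaluated on the signed distance
d = site - rbp_pos (negative distances use the upstream range l_up);
activator mode uses (1 + f) factors. Only an exon's own two splice sites
are modulated. Splice-site coordinates: each exon's 3'SS is its start and
5'SS its end; the fixture exon starts (180/300/600 nt) are interpolated,
non-canonical defaults — printed values exist only for the exon ends
(210/443/690) and gene length (700).

A consequence of this structure worth knowing: fully silencing an OUTER
exon routes bound transcripts into retention, which PSI excludes, so PSI
asymmetry analyses around 5' splice sites are informative at the cassette
exon's sites (where silencing redirects flux to skipping) and are run at
slow elongation (fixture vpol = 5 nt/s) so that exon-definition rates
compete on the timescale of the deposition-window delays.

## Stochastic engine

Direct-method Gillespie over zero-/first-order reactions with activity
windows. When a sampled waiting time crosses the next window boundary, the
clock advances to the boundary and the waiting time is redrawn — exact by
memorylessness, and verified distributionally against a thinning sampler
(KS test) and against exponential survival on a pure-death toy. Kernels are
numba-compiled; each run seeds the kernel RNG with a per-run seed derived
via `SeedSequence` from the root seed, making ensembles bit-reproducible
and order-independent. Runs whose Incl+Skip is zero have undefined PSI and
are excluded from the ensemble mean/std but counted. For the mechanistic
model the binomial comparison uses the per-run spliced total (Incl+Skip) as
the trial count, which corrects for retention.

## Bursting and feedback

Promoter toggles kon/koff; initiation Vsyn while on; 8-step elongation;
inclusion commitment from every P_i into a committed I-chain that keeps
elongating and matures into the Incl pool at chain end (the alternative,
instant maturation, changes only the maturation latency); basal skipping
from P8; feedback channel with per-P8 propensity Fb_s/(1+(K/Skip)^N), zero
when Skip = 0 — the intermediate escaped state is lumped away (fast exit),
so the feedback reaction converts P8 directly to Skip. Isoform-specific
degradation d_i, d_s. The deterministic counterpart treats the promoter as
a continuous two-state occupancy and evaluates the feedback on continuous
Skip; with feedback off the network is linear and its stationary state has
the closed form implemented in `stationary_psi_no_feedback` (reach-P8
probability q^7 with q = kelong/(kelong+ki)).

PSI(t) is sampled on a uniform grid (default 10,000 points) so histograms
weight states by residence time; the first 10% of points are discarded as
transient. Mode detection: `scipy.stats.gaussian_kde` with Scott's rule
(bandwidth n^(-1/5) times sample std in 1-D) on [0, 1] including the
boundaries, maxima below 5% of the peak density ignored, and neighboring
maxima merged when the valley between them exceeds 90% of the lower peak —
KDE roughness and small-count PSI atoms (values exactly 0, 1/2, 1) would
otherwise masquerade as modes. Antimodes are the minima between surviving
modes, so modes and antimodes always interleave.

Fixture parameters follow the documented scan procedure (start from equal
rates; raise ki and d_i, lower ks and d_s for the bursting regime; choose
N > 3, K at a skipping level rarely reached without feedback, then scan
Fb_s): bursting regime kon 0.002, koff 0.01, Vsyn 1, ki 0.2, ks 0.05,
d_i 0.05, d_s 0.002 (two modes, one at PSI = 0); feedback regime Vsyn 0.3,
ki 0.1, ks 0.02, d_i = d_s = 0.01, Fb_s 0.3, K 8, N 6 (two modes); combined
regime kon 0.004, d_s 0.008, Fb_s 2, K 10, N 6 over 4e5 s (three modes at
roughly 0 / 0.39 / 0.85). In the combined regime the faster d_s lets the
skipping pool stabilize during feedback-on bursts, which is what separates
the intermediate mode from the PSI = 0 peak. All these values are
reconstructed defaults, seed-robust in the tests (e.g. 24/24 seeds give
three modes for the combined fixture).

## Chromatin-release competition

Single intron: no_steps elongation competitions (ki vs kelong) followed by
a terminal 3'-end state where splicing competes with release (ki vs tr),
giving %spliced = 100 [1 - (kelong/(ki+kelong))^no_steps tr/(ki+tr)].
Observable conversion: kelong = pol_speed no_steps / transcript_length;
tr = 1/dwell_time; ki = prerelease_fraction/(L/pol_speed + dwell_time)
with the pre-release spliced share expressed as a fraction in [0, 1] (the
quantity is often quoted in percent; the conversion uses the fraction so ki
carries 1/s). no_steps defaults to 8 and is configurable. The stochastic
estimate samples the embedded jump chain exactly (vectorized binomial
cascade over states) — for a first-order absorbing chain this has the
identical absorption distribution as wall-clock Gillespie simulation, which
the tests confirm against the generic engine. Shipped observables are
synthetic demonstrations, labeled as such; measured condition tables are
supplied by the user via config.

## What the fixtures do and do not show

The synthetic fixtures emulate the geometry of a three-exon minigene and
physiologically plausible rate scales (splicing commitment over seconds to
minutes, vpol 1-1000 nt/s). They reproduce the qualitative phenomenology —
the four PSI-velocity response classes, the dual activator/inhibitor RBP
role, binomial splicing noise, multimodality from bursting/feedback — but
no fixture encodes measured rate constants, so passing tests demonstrate
internal consistency and mechanism, not quantitative agreement with any
particular gene. Real nascent-transcript data additionally contain
features the generator omits: variable elongation speed along the gene,
peaked (non-exponential) splicing-time distributions, extrinsic noise in
RBP abundance, and coupled transcription-splicing feedback.

## Numerical choices

LSODA with rtol 1e-8/atol 1e-10 throughout (stiffness never binds at these
sizes); matrix exponentials via `scipy.linalg.expm` on 19-80 state
matrices; inflection detection by central differences of PSI against
log10(vpol) (the transition spans decades of velocity, so the log axis is
the natural one); shape classification compares endpoints and interior
extrema with a 0.02 PSI tolerance (below the resolution at which response
classes are distinguished experimentally); profile grids default to
log-spaced 1-1000 nt/s. Degenerate inputs (all-zero commitment rates,
empty grids, unsorted grids, windows outside scans) raise explicit errors;
PSI of an outcome with no spliced mass is NaN with a guarded accessor.
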