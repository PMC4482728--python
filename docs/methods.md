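# Methods

This note documents the model, the numerical machinery and the design
choices behind `assortlif`, including what the synthetic networks do and
do not capture.

## Model and assumptions

The network is purely excitatory: `N` leaky integrate-and-fire neurons
(membrane time constant `tau = 20 ms`, refractory period
`tau_ref = 2 ms`, reset `V_reset = 10 mV`, synaptic amplitude
`J = 0.1 mV`) coupled by delta-pulse synapses with per-edge delays drawn
uniformly on [0, 6] ms. The firing threshold is `theta = 20 mV`; it is
exposed as a configuration field because the standard cortical
("Brunel-style") parameterization that the other constants follow places
the threshold 10 mV above reset. The derived threshold rate is
`nu_thr = theta/(J*tau) = 10 spikes/ms` (10 kHz); stimuli `s` are
external Poisson rates in units of `nu_thr`, so `s < 1` cannot drive an
isolated neuron to fire on mean input alone.

The mean-field reduction assumes (i) neurons within an in-degree class
are statistically exchangeable, (ii) inputs are asynchronous and dense
enough for the diffusion approximation (Gaussian current with matched
first two moments), and (iii) the network is large and random enough
that the joint degree matrix `N_kk'` summarizes all relevant structure.
Under these assumptions each class obeys the Siegert rate equation with
`mu_k = J*tau*(nu_thr*s + sum_k' N_kk' r_k')` and `sigma_k^2 = J*mu_k`,
coupled across classes.

Internally all computation is in mV and ms; rates in spikes/ms. Every
public interface reports rates in Hz. This is worth stating once because
`nu_thr` in Hz is 10,000 — a classic source of unit bugs.

## Degree structure

In-degrees follow the discrete truncated power law `P(k) = Z k^alpha` on
integers `[k_min, k_max]` (normalized by the discrete sum, not an
integral), with out-degree equal to in-degree per node — the empirically
motivated convention that also allows fully segregated assortative
networks. Closed-form kernels are provided for independent in/out
degrees (`f(k,k') = P(k')`), the uncorrelated equal-in/out network
(`f(k,k') = k'P(k')/<k>`), the maximally assortative delta kernel
(`f = delta(k,k')`) and a disassortative delta fit
(`f = delta(k, k_min*k_max/k')`, with the generally non-integer partner
mapped to the nearest supported degree, ties toward the smaller degree —
the mapping is itself a fit of peak positions, so nearest-degree rounding
is within its accuracy). Kernels can also be sampled from any adjacency;
in that case one population per distinct realized in-degree is used (up
to 491 classes for [10, 500]), with optional logarithmic binning
(`bin_kernel`) that merges classes weighted by node fractions and labels
each bin by its mean degree, preserving the row-sum identity
`sum_k' N_kk' = k` exactly.

## Network construction and rewiring

The directed configuration model pairs in- and out-stubs uniformly and
then removes self-loops and duplicate edges (~2% of stubs for the
default distribution at N = 1e4), so realized degrees sit slightly below
targets; all degree classes are recomputed from the realized graph.
Degree correlations are imposed by Metropolis target swaps: two random
edges exchange targets, accepted with probability `g` only when the swap
moves the in-degree covariance of the edge ends in the desired direction
(strict inequality) and with probability `1-g` unconditionally. Swaps
that would create a self-loop or duplicate edge are rejected and count
as attempts, keeping the chain simple and exactly degree-preserving.
Membership tests run through an open-addressing hash set with tombstone
deletion and periodic rebuild; the Pearson coefficient is tracked online
(only the cross-moment changes under a target swap), enabling cheap
plateau detection and stop-at-target-p snapshots.

The default attempt budget is 100·|E| with a plateau stop (p change
below 1e-3 over 10·|E| attempts). Saturation runs (the "maximally
assortative/disassortative" networks) use 600·|E| with a tighter plateau
(1e-4 over 20·|E|), because the greedy chain's tail is slow and the
looser rule halts visibly short of the plateau.

### Correlation coefficient convention

The link-end in-degree correlation is computed as the sample Pearson
correlation of (origin in-degree, target in-degree) over directed edges.
The textbook undirected formula expresses the same quantity through the
*excess* degree distribution `Q(k) = (k+1)P(k+1)/<k>`; because shifting
both edge-end variables by a constant leaves a correlation unchanged,
the consistent excess-convention estimator and the plain edge-sample
estimator coincide, and only this consistent form is bounded by [-1, 1]
and equal to 1 on a perfectly assortative graph. A literal mixed
evaluation (edge-counted joint over full degrees against the shifted
marginal) is kept as the diagnostic `pearson_literal_shifted`; it
overshoots 1 on strongly assortative graphs and is not used for results.

### Finite-size ceilings at N = 1e4

Two desk-scale effects are worth knowing. First, duplicate removal makes
the configuration model slightly disassortative, p ≈ -0.02 at N = 1e4
(scaling like `<k^2>/(N<k>)`; at N = 1e5 it is -0.003, matching the
reference value). Second, the assortative chain saturates near p ≈ 0.81
at N = 1e4: a degree-k class can only wire internally without duplicate
edges if it has more than k members, which fails for k ≳ 47 at this
size, so high-degree links must spread across neighboring classes. At
N = 1e5 the same chain reaches p ≈ 0.995. Desk-scale assortative
"extremes" are therefore ceilings of the construction, not of the
implementation.

## Siegert evaluation and fixed points

The Siegert integrand `e^{x^2}(1+erf x)` equals `erfcx(-x)`, evaluated
without overflow as `exp(x^2)*erfc(x)` for moderate arguments, an
asymptotic series beyond |x| = 6, and the reflection
`erfcx(-x) = 2 e^{x^2} - erfcx(x)` for positive x. The integral uses
composite Gauss–Legendre panels sized to the local steepness of
`e^{x^2}` plus an analytic antiderivative for the deep tail x < -6; for
upper limits above 8 the integral exceeds e^64 and the rate is returned
as zero (it is below 1e-26 spikes/ms). The numba kernel agrees with an
independent scipy `erfcx` + adaptive-quadrature reference to ~1e-10
relative, which the tests check property-style; `sigma = 0` falls back
to the noiseless closed form
`1/(tau_ref + tau*ln((mu-V_reset)/(mu-theta)))`.

Fixed points of the coupled equations are found by iterating the
relaxation map `r <- r + (dt/tau_x)(Phi(r) - r)` with `tau_x = 3 ms` and
`dt = tau_x` by default — i.e. plain Picard iteration, which has the
same fixed points as any damped step and converges ~3x faster than a
1/3-damped one; `dt` remains configurable for users who want the
literal relaxation dynamics. Anderson acceleration (depth 5, clipped to
[0, 1/tau_ref]) typically converges in ~10 iterations; near a fold,
where the accelerated iteration chases the ghost of a vanished fixed
point, the solver detects stagnation and falls back to pure Picard,
which is the monotone relaxation dynamics itself and reliably collapses
to the remaining (quiescent) solution. Convergence demands a fixed-point
residual below 1e-6 Hz per class; non-convergence raises with the
residual attached.

The upper (active) branch is selected by initializing at
`0.8/tau_ref = 400 Hz` and, for response curves, sweeping the stimulus
downward by continuation from the largest s, each solve warm-started
from its neighbor. The curve records the degree-weighted mean rate and
the degree-weighted standard deviation `sigma(s)` of class rates
(weighting by class node fractions is the default; the unweighted
variant can be formed from the stored per-class rates). The stimulus
threshold is reported as the midpoint of the grid interval across which
the mean rate rises through 0.1 Hz (the dead-network epsilon), with the
grid step (0.02 by default) as its uncertainty. Below the fold, upward
and downward continuation may disagree (bistability); the branch label
is always attached to the curve, and only downward curves define
thresholds.

## Direct simulation

The simulator is forward Euler at dt = 0.01 ms with spike delivery
through per-target circular buffers; delays are rounded to the grid (and
floored at one step so an edge can never act within its source's firing
step). External input is a per-neuron Poisson event count per step
(inverted from one uniform draw; the event rate per step is ~0.1), each
event depolarizing by J. During the refractory period the membrane is
clamped at `V_reset` and inputs are discarded — the standard convention;
the alternative (accumulating during refractoriness) would raise rates
slightly at high drive. Initial voltages are uniform on
[V_reset, theta); spikes are counted after a 200 ms burn-in over a 1 s
window. Per-class rates from a 10^4-neuron simulation at s = 1.2 agree
with the mean-field solution to ~1% (the tests require 10%, evaluated on
classes with at least 10 members so that single-neuron shot noise does
not masquerade as model error).

Known accuracy limits: the diffusion approximation carries an
O(J/sigma) finite-pulse bias (~1% here, visible as a systematic ~0.5-1%
rate deficit of the simulation relative to the Siegert prediction), and
halving dt moves network rates by well under 1%. Test tolerances for
simulator-vs-theory comparisons therefore combine statistical error with
a 1.5% systematic allowance rather than pretending the approximation is
exact.

## Mutual information

The readout is the mean rate of `n = 5000` randomly sampled neurons,
modeled as Gaussian with mean `r(s)` and variance `sigma^2(s)/n`, under
a uniform stimulus prior on (0, 1). Stimuli whose mean-field rate falls
below 0.1 Hz are treated as exactly quiescent: their response is a point
mass at zero, not a narrow Gaussian. The primary evaluation integrates
the defining double integral directly: per-stimulus Gauss–Hermite
expectations of the log density ratio against the marginal mixture, plus
the exact atom term `w0*log2(1/w0)`. This form is an average of
Kullback–Leibler divergences and hence nonnegative by construction, and
it handles the dead-network atom that makes the small-noise expansion
ill-defined (its change-of-variables density requires `dr/ds > 0`). The
expansion `I = H - H_noise` is implemented alongside: flat segments of
the response curve are assigned to discrete symbols contributing
`-w*log2 w` to `H` (and their noise entropy only where `sigma > 0`),
derivatives come from central differences on the stimulus grid, and a
negative result is flagged, never clipped.

One numerical caveat governs grid choices: the direct method treats each
stimulus grid point as a mixture component, so the spacing of adjacent
response means must stay below the readout noise scale `sigma/sqrt(n)`
or the discretized channel looks more informative than the continuum.
Assortativity sweeps therefore solve the response curve on a 0.0025
stimulus grid by default (the continuation-with-warm-start solver makes
the 400 extra solves cheap). The Gaussian `sigma^2/n` model itself
assumes `n << N`; at `n = 5000` of `N = 1e4` the finite-population
correction to sampling without replacement is a factor ~2 in variance,
which is a property of the readout model inherited from the large-N
setting, not of this implementation.

The assortativity ladder is produced in a single pass: one
configuration-model network, rewired by the g = 1 assortative chain with
snapshots taken as the online p crosses each requested level (the chain
is monotone at g = 1, and the fine checkpoint interval keeps overshoot
below ~0.01). Unreachable levels saturate at the ceiling described
above and are reported with the achieved p.

## What the synthetic networks do not capture

The generator reproduces the study conditions — truncated power-law
in-degrees, equal in/out degree per node, tunable in-degree
assortativity, uniform delays — and nothing else. Real cortical
networks additionally have inhibition, in/out-degree correlations
beyond strict equality, spatial structure, clustering, synaptic weight
heterogeneity and plasticity; none of these are modeled, so passing
tests demonstrate the correctness of the method under its stated
assumptions, not the biological completeness of the model. The
mean-field theory itself assumes asynchronous firing; the random delays
exist precisely to suppress synchronized cascades in the simulator, and
the steady-state equations are independent of them.

## Problem sizes used by tests and the acceptance script

Networks of N = 1e4 (the desk scale at which all scale-sensitive
quantities are quoted), one-second simulations at dt = 0.01 ms,
rewiring budgets up to 600·|E| attempts, stimulus grids of 0.02 (curves,
thresholds) and 0.0025 (information sweeps), and 5000-neuron readouts.
These sizes were chosen so that the full pipeline — generation,
rewiring, mean-field continuation, simulation and the two-exponent
information sweep — completes in minutes on a single core while keeping
every qualitative regime of the full-scale study (sub-threshold
quiescence, the fold, the assortativity optimum) clearly resolved.
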