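# assortlif

Firing rates and information transfer of degree-correlated networks of
leaky integrate-and-fire (LIF) neurons.

Cortical networks are heterogeneous: a few richly connected neurons carry
much of the activity, and neurons of similar connectivity tend to wire
together (assortative degree correlations). This package asks how those
two structural features shape the response of a recurrent excitatory
network to a weak common stimulus, and how much information the
population rate carries about that stimulus. It is aimed at computational
neuroscientists and network scientists who want a fast, tested
implementation of the k-population mean-field method together with the
network-construction and verification machinery around it.

## The model

Each neuron follows LIF dynamics
`tau dV/dt = -V + R I(t)`, firing and resetting from threshold `theta` to
`V_reset` with refractory period `tau_ref`; synaptic events are delta
pulses of amplitude `J`. Every neuron receives an independent external
Poisson train of rate `s * nu_thr`, where `nu_thr = theta/(J tau)` is the
rate at which mean drive alone reaches threshold, so `s < 1` is the
sub-threshold regime in which activity must be sustained by recurrence.

Neurons are grouped into populations by in-degree `k`. In the diffusion
approximation the stationary rate of each class obeys the coupled
self-consistent (Siegert) equations

```
r_k   = [ tau_ref + tau*sqrt(pi) * INT_{(V_reset-mu_k)/sigma_k}^{(theta-mu_k)/sigma_k} e^{x^2}(1+erf x) dx ]^-1
mu_k  = J*tau*( nu_thr*s + SUM_k' N_kk' r_k' ),    sigma_k^2 = J*mu_k
```

where `N_kk' = k f(k,k')` is the joint degree distribution: the average
number of inputs a `k`-neuron receives from `k'`-neurons. All structural
information enters through this single matrix, which can be sampled from
an adjacency or taken from closed forms (uncorrelated, maximally
assortative/disassortative kernels).

Networks carry a truncated power-law in-degree distribution
`P(k) = Z k^alpha` on `[k_min, k_max]` with equal in- and out-degree per
node, built by a directed configuration model and rewired toward a target
Pearson in-degree correlation `p` with degree-preserving Metropolis
target swaps. A direct forward-Euler simulator of the full spiking
network serves as the verification oracle. The stimulus/response mutual
information of the population readout (mean rate of `n` sampled neurons,
Gaussian with variance `sigma^2/n`) is computed both by direct quadrature
and by the small-noise expansion `I = H - H_noise`.

## Worked example

```python
import numpy as np
import assortlif as al

params = al.NeuronParams()            # tau=20 ms, tau_ref=2 ms, theta=20 mV,
                                      # V_reset=10 mV, J=0.1 mV
dist = al.truncated_powerlaw(-2.0, 10, 500)
print(al.degree_moments(dist))        # -> (38.42, 3283.02)

seq = al.sample_degree_sequence(dist, 10_000, seed=0)
net = al.configuration_model(seq, seed=1)
print(al.pearson_in_degree_correlation(net).p)   # -> -0.0208 (uncorrelated)

kern = al.sample_joint_degree(net)    # N_kk' from the adjacency
sol = al.solve_selfconsistent(kern, s=1.2, params=params)
print(sol.mean_hz())                  # -> 71.4  (network mean rate, Hz)

curve = al.response_curve(
    al.analytic_kernel(dist, "uncorrelated_equal_inout"),
    np.arange(0, 1.21, 0.02), params, direction="down",
)
print(al.stimulus_threshold(curve))   # -> (0.79, 0.02): activity dies at s~0.8
```

The mean rate of 71.4 Hz agrees with the direct spiking simulation of the
same network to about 1% per degree class; the threshold `s ~ 0.8` is the
fold below which the uncorrelated network cannot sustain activity.
Assortative rewiring pushes this threshold toward zero while broadening
the firing-rate distribution; the trade-off gives the mutual information
an interior optimum:

```python
df = al.assortativity_sweep(dist, np.arange(0, 0.91, 0.05), n=5000,
                            params=params, seed=0, N=10_000)
print(df.loc[df.I_bits.idxmax(), ["p_achieved", "I_bits"]])
# -> p_achieved 0.55, I_bits 3.58 (optimum at intermediate assortativity)
```

A command-line interface mirrors the library
(`assortlif net generate|rewire|stats`, `mf solve|response`, `sim run`,
`mi sweep`, `repro figures`).

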