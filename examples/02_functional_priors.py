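"""Functionally-informed fine-mapping with annotation enrichment.

Simulates 12 loci whose causal variants preferentially fall in annotated
regions (enrichment log-odds W=2, i.e. e^2 ~ 7.4-fold).  Enrichment weights
are estimated jointly from the signal PIPs pooled across loci — single-locus
soft counts (a handful of causal variants) are far too noisy — then each
locus is re-fitted with the informed prior.
"""

import numpy as np

from finemapvi import (
    AnnotationMatrix,
    SimulationConfig,
    auprc,
    estimate_weights,
    fit,
    signal_pip,
    simulate_locus,
    softmax_prior,
    weight_to_fold,
)

sims, states, sig = [], [], []
for i in range(12):
    cfg = SimulationConfig.reduced(n=25_000, g=200, k_causal=5,
                                   w_intensity=2.0, seed=130 + i)
    sim = simulate_locus(cfg)
    state = fit(sim.locus, k=10)
    sp = signal_pip(state.groups, sim.locus.ld)
    sims.append(sim)
    states.append(state)
    sig.append(sp if sp is not None else np.zeros(cfg.g))

pooled = AnnotationMatrix(sims[0].anno.names,
                          np.vstack([s.anno.values for s in sims]))
enr = estimate_weights(pooled, np.concatenate(sig))
print("joint enrichment estimates from pooled signal PIPs "
      "(G-test screens relevance):")
for name, w, p, sel in zip(enr.names, enr.weights, enr.p_value, enr.selected):
    mark = "*" if sel else " "
    print(f" {mark} {name:18s} w={w:+5.2f} (fold {weight_to_fold(w)[0]:5.2f})  "
          f"p={p:.2e}")
print("(*) p < 1e-5, used for the informed prior; "
      "enriched annotations carry simulated log-odds 2\n")

sel = enr.selected
w_sel = estimate_weights(
    AnnotationMatrix([pooled.names[j] for j in np.flatnonzero(sel)],
                     pooled.values[:, sel]),
    np.concatenate(sig)).weights

flat_auprc, info_auprc = [], []
for sim, state in zip(sims, states):
    prior = softmax_prior(sim.anno.values[:, sel].astype(float), w_sel)
    informed = fit(sim.locus, priors=prior, k=10)
    flat_auprc.append(auprc(state.pip(), sim.truth))
    info_auprc.append(auprc(informed.pip(), sim.truth))

print("AUPRC ranking variants by PIP against true causal status "
      "(mean over the 12 loci):")
print(f"  statistics only     : {np.mean(flat_auprc):.3f}")
print(f"  with informed prior : {np.mean(info_auprc):.3f}")
ratio = np.exp(sim.anno.values[:, sel].astype(float) @ w_sel)
print(f"  prior max/min ratio : {ratio.max() / ratio.min():.1f} "
      "(1.0 would mean a flat prior)")
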