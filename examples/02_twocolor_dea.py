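"""Differential expression from raw two-colour signals.

Simulates one resistant-vs-susceptible comparison (six arrays, half
dye-swapped, an intensity-dependent dye bias, 100 probes planted at a
twofold change), runs the full normalisation + moderated-t pipeline and
reports how many planted probes are recovered at q <= 0.05.
"""

from resistex import SimulationConfig, run_dea
from resistex.simulate import simulate_raw_signals

cfg = SimulationConfig(
    seed=7, n_transcripts=2000, n_planted_up=60, n_planted_down=40,
    planted_log2fc=1.0, module_specs=[], noise_sd=0.5, arrays_per_dataset=6,
)
arrays, truth = simulate_raw_signals(cfg)
results = run_dea(arrays)  # MA -> loess -> Aquantile -> moderated t -> BH

planted = truth.planted_up | truth.planted_down
hits = [r for r in results if r.q_value <= 0.05]
true_hits = [r for r in hits if r.probe_id in planted]
print(f"arrays: {len(arrays)} ({sum(a.dye_swapped for a in arrays)} dye-swapped)")
print(f"probes significant at q<=0.05: {len(hits)}")
print(f"  of which planted: {len(true_hits)} / {len(planted)} planted probes")
top = max(results, key=lambda r: abs(r.t_mod))
print(f"top probe {top.probe_id}: fold change {top.fold_change:.2f}, "
      f"moderated t {top.t_mod:.1f}, q {top.q_value:.2e}")
print("Power near 1 and few extra hits means the dye bias was removed and the")
print("variance moderation is calibrated.")
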