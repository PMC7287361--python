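"""Cross-recurrence analysis of one strongly and one weakly coupled dyad.

Preprocesses each dyad's learning-phase signals (8 Hz, z-scored), selects
embedding parameters per dyad, calibrates the radius into the 2-4%
recurrence band and prints the four line metrics side by side.
"""

from dyadsync import DesignConfig, generate_dataset, run_crqa
from dyadsync.preprocess import crqa_ready

for label, kappa, seed in (("weakly coupled", 0.1, 1),
                           ("strongly coupled", 0.9, 2)):
    ds = generate_dataset(DesignConfig(n_dyads=2, n_blocks=1, seed=seed),
                          coupling_sampler=lambda rng: kappa, seed=seed)
    rec = ds.dyads[0].blocks[0]
    demo = crqa_ready(rec.trace("demonstrator", "learning"))
    obs = crqa_ready(rec.trace("observer", "learning"))
    m = run_crqa(demo, obs)
    p = m.params
    print(f"{label} (kappa={kappa}):")
    print(f"  embedding: delay={p.delay} samples, dim={p.dim}, "
          f"radius={p.radius:.3f} z-units -> RR={m.rr:.3f}")
    print(f"  DET={m.det:.3f}  LAM={m.lam:.3f}  maxL={m.maxl}  "
          f"rENTR={m.rentr:.3f}")
# DET/LAM report the fraction of recurrent points in diagonal/vertical
# lines, maxL the longest uninterrupted co-evolution. A strongly coupled
# dyad shows markedly longer diagonal structure at the same recurrence
# density.
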