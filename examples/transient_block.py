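"""The transient-block experiment: why cleft topology matters.

Stimulates the tight and leaky 2D cross meshes twice each at a 340 ms
coupling interval (conductivity tuned to an effective 17 cm/s).  The first
wave travels through recovered tissue and crosses the fibrotic row in both
meshes; the premature second wave is stopped by the tight topology but
leaks diagonally through the leaky one.

Takes a few minutes: each run integrates human ventricular kinetics at a
20 microsecond step over ~660 ms of activity on a 2888-element mesh.
"""

from fibroclefts.protocols import run_block_experiment

for topology in ("tight", "leaky"):
    out = run_block_experiment(topology)
    print(f"{topology:>5}: sigma = {out['sigma']:.3f} mS/cm, "
          f"wave 1 {out['waves']['wave1']}, wave 2 {out['waves']['wave2']}")

# Expected output: both topologies let wave 1 cross; only the tight
# topology blocks wave 2.  Transient block is a known precursor of reentry,
# so a splitting algorithm that leaks current across clefts (the leaky
# assignment) underestimates the arrhythmogenicity of the fibrosis.
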