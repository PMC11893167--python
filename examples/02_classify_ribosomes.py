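"""Classify ribosomes by membrane context: import-oriented or not.

A ribosome is import-oriented when its peptide exit tunnel lies within 95 A
of the outer membrane; merely having its center within 250 A makes it
proximal-non-import.  The sweep reproduces the 0-120 A cutoff exploration
used to calibrate the threshold.
"""

from mitomorph import (
    compute_context,
    decorate_particles,
    make_mitochondrion,
    summarize_classes,
    sweep_exit_cutoff,
)

omm, imm, _ = make_mitochondrion(radius=3000.0, spacing=135.0, subdivisions=5, seed=1)
particles, truth = decorate_particles(omm, n=500, import_fraction=0.4, seed=2)

records = compute_context(particles, omm)
summary = summarize_classes(records)

print("class counts:", summary["counts"])
print(f"import fraction among near-membrane ribosomes: "
      f"{100 * summary['import_fraction']:.0f}%")
print("\nexit-cutoff sweep (import counts):")
print(sweep_exit_cutoff(records, [80, 95, 110, 120]).to_string(index=False))
# The planted fraction is 0.4; the raw rate is higher because randomly
# oriented particles occasionally point their exit at the membrane by chance.
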