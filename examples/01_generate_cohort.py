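"""Generate a synthetic thermal-wound cohort and look at what is in it.

The generator produces pseudo-colour thermal images of a leg with an
elliptical wound.  The two outcome classes differ only in the texture of
the wound bed: unhealed wounds get a rougher, more skewed temperature
field (shorter spatial correlation), healed wounds a smoother one.

Run:  python examples/01_generate_cohort.py
"""

from pathlib import Path

from woundtherm import SyntheticParams, generate_cohort, write_cohort

out = Path("examples/output/cohort")
params = SyntheticParams()  # 160x120 frames, ironbow palette

cohort = generate_cohort(n_unhealed=8, n_healed=4, params=params, seed=42)
manifest = write_cohort(cohort, out, seed=42)

print(f"wrote {len(cohort)} PNGs to {out}")
print(f"manifest: {manifest}")
for img in cohort[:3] + cohort[-2:]:
    print(f"  {img.subject_id}: label={img.label}, shape={img.rgb.shape}")
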