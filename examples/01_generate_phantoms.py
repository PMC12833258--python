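"""Generate a small synthetic low-contrast dataset and inspect it.

The phantom generator renders a grayscale slice containing an elliptical
organ (class 1) with one or two irregular lesions inside it (class 2) on
a noisy background (class 0). Class offsets shrink with the ``contrast``
parameter, which is what makes the segmentation problem hard.

Run:  python examples/01_generate_phantoms.py
"""

from pathlib import Path

import numpy as np

from hfseg import PhantomSpec, generate_phantom, read_dataset, write_dataset

out_dir = Path("scratch/example_dataset")

# A 64x64 spec trains quickly on CPU; contrast 0.6 keeps the lesion only
# slightly brighter than the surrounding organ tissue.
spec = PhantomSpec(size=64, contrast=0.6, noise_std=0.02)

samples = [generate_phantom(spec, seed) for seed in range(12)]
for s in samples[:3]:
    frac = {c: np.count_nonzero(s.mask == c) / s.mask.size for c in (0, 1, 2)}
    print(f"seed={s.seed}: background {frac[0]:.2%}, "
          f"organ {frac[1]:.2%}, lesion {frac[2]:.2%}")

# Datasets round-trip losslessly through 16-bit image PNGs, paletted
# mask PNGs and a TSV manifest.
write_dataset(samples, out_dir)
back = read_dataset(out_dir)
assert all(np.array_equal(a.mask, b.mask) for a, b in zip(samples, back))
print(f"wrote and re-read {len(back)} image/mask pairs in {out_dir}/")
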