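#!/usr/bin/env python
"""Generate the synthetic study material used by the downstream analyses.

Produces (a) a cline-structured specimen table — ordinal characters tied
to altitude through a latent-threshold model, RGB variables darkening
linearly with altitude, latitudes clumped into four collection areas —
and (b) a small set of patch images with landmark files and known true
colors under varying exposure.  Tables go to results/; images (binary)
go to scratch/.
"""

from pathlib import Path

import numpy as np

from morphocline.imagecolor import save_image
from morphocline.io import write_tps
from morphocline.synth import (
    ClineParams,
    SyntheticImageSpec,
    gen_cline_matrix,
    gen_specimen_images,
    inject_missing,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "synthetic_images"
SEED = 11


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    params = ClineParams(
        n_specimens=50,
        n_rgb_points=26,
        latent_rho=(0.0, 0.2, 0.4, 0.6, 0.8),
        n_ordinal_states=(2, 3, 3, 4, 3),
        rgb_slopes=(-45.0, -40.0, -30.0),
        noise_sd=8.0,
        seed=SEED,
    )
    table, truth = gen_cline_matrix(params)
    rgb_cols = [c for c in table.columns if c.startswith("p")]
    table[rgb_cols] = inject_missing(table[rgb_cols], 174 / 3900, seed=SEED)
    n_missing = int(table[rgb_cols].isna().sum().sum())
    table.to_csv(RESULTS / "synthetic_specimens.csv", index=False)
    print(f"wrote {len(table)} specimens x {len(table.columns)} columns "
          f"({len(rgb_cols)} RGB variables, {n_missing} missing cells) "
          f"-> results/synthetic_specimens.csv")
    print(f"generating latent correlations with altitude: {truth['latent_rho']}")
    print(f"generating RGB slopes per 1000 m: {truth['rgb_slopes']}")

    rng = np.random.default_rng(SEED)
    records = []
    for i, mult in enumerate((1.0, 0.8, 1.05, 0.6, 0.9)):
        # a large dark "body" disc dominates the darkest-45% foreground;
        # the landmarked sample patches sit inside it (overlap intended)
        body = (80, 60, 55, (70, 55, 45))
        sample_patches = [
            (50 + 60 * (j % 2), 40 + 40 * (j // 2), 7,
             tuple(int(v) for v in rng.integers(20, 180, 3)))
            for j in range(4)
        ]
        spec = SyntheticImageSpec(
            width=160, height=120,
            patches=[body] + sample_patches,
            exposure_multiplier=mult,
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # body/patch overlap is the design
            img, lm, truth_colors = gen_specimen_images(spec, seed=SEED + i)
        # landmark only the sample patches, not the body
        lm["landmarks"] = lm["landmarks"][1:]
        # cuticle-like texture everywhere except the sampled discs, so
        # tone-curve matching is not limited by flat-patch quantization
        noise = rng.integers(-6, 7, img.shape[:2])
        keep = np.zeros(img.shape[:2], bool)
        yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
        for (cx, cy, r, _c) in sample_patches:
            keep |= (xx - cx) ** 2 + (yy - cy) ** 2 <= (r - 2) ** 2
        noise[keep] = 0
        img = np.clip(img.astype(int) + noise[:, :, None], 0, 255).astype("uint8")
        save_image(img, SCRATCH / f"spec{i}.png")
        lm["image"] = f"spec{i}.png"
        records.append(lm)
        print(f"  image spec{i}.png: exposure x{mult}, "
              f"true colors {truth_colors[1:]}")
    write_tps(records, SCRATCH / "landmarks.tps")
    print(f"wrote 5 images + landmarks.tps -> {SCRATCH}")


if __name__ == "__main__":
    main()
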