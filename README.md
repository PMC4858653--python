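# adaptscan

Feature-adaptive two-pass scanning for scanning electron microscopy (SEM),
as a reusable Python library and CLI with a simulated acquisition model in
place of the microscope.

## The problem

In SEM the pixel-dwell time sets both the signal-to-noise ratio (shot noise
falls as 1/√dwell) and the total acquisition time and electron dose. For
large serial-section (FIB/SEM) volumes or dose-sensitive specimens, uniform
Cartesian scanning wastes most of its dose on featureless regions.
`adaptscan` implements an image-based adaptive scheme:

1. **Initial scan** — a quick full raster at a small dwell `t_initial`
   (e.g. 300 ns) produces a noisy overview image.
2. **Mask generation** — the gradient magnitude of a Gaussian-smoothed
   version of that image is thresholded (256-bin histogram running sum) so
   that a fraction *A* of pixels with the strongest gradients — the
   **high-interest area (HIA)**, mainly phase boundaries — is selected.
3. **Sparse rescan** — only HIA pixels are revisited row by row
   (blank/unblank semantics, serialized as an ASCII stream file) at a long
   dwell `t_sparse` (e.g. 27 µs).
4. **Adaptive filtering** — the smooth remainder (**filter region**) is
   denoised with a per-pixel masked Gaussian: the kernel is multiplied by
   the local mask, restricted by a flood fill to the connected
   filter-region patch around the target pixel, and renormalized to unit
   sum, so it never averages across the HIA or into a different phase.
5. **Fusion** — HIA pixels take the sparse-scan values; optionally the raw
   initial signal is mixed back into the filter region with weight
   `i = √(t_initial / t_sparse)` so both regions end up with the same
   residual noise level ("noise-level adaptation").

The average dwell is `t_avg = t_initial + A · t_sparse`; with the defaults
(300 ns, A = 0.1, 27 µs) that is 3 µs per pixel, yet the reconstruction
reaches several times the SNR of a uniform 3 µs scan — equivalently, a
uniform scan would need an order of magnitude more dose to match it.

Acquisitions are simulated with per-pixel Poisson counting noise on
synthetic two-phase phantoms (nodular or lamellar dark inclusions in a
bright matrix, emulating cast-iron micrographs), so every claim can be
checked against a noise-free ground truth.

## Worked example

```bash
adaptscan compare --size 512 --seed 1 --t-initial 3e-7 --t-sparse 2.7e-5 \
    --area 0.1 --edge-sigma 3 --filter-sigma 10
```

simulates the full benchmark on a 512×512 nodular phantom and evaluates
four scan modes at the same 3 µs average dwell against a simulated 60 µs
reference scan (values are from an actual run; pixel errors in % of the
reference maximum):

| method | mean pixel error | SNR | PSNR | SSIM |
|---|---|---|---|---|
| adaptive | 0.26 % | 248 | 47.8 dB | 0.988 |
| adaptive + noise adaptation | 0.42 % | 157 | 43.9 dB | 0.964 |
| uniform | 1.02 % | 64 | 36.1 dB | 0.810 |
| uniform + anisotropic diffusion | 0.32 % | 139 | 42.8 dB | 0.987 |

The adaptive reconstruction beats uniform scanning on every metric at equal
dose; switching noise adaptation on deliberately re-introduces shot noise
(raising the pixel error) so that the filter region and the HIA have the
same noise texture. The anisotropic-diffusion comparator closes much of
the gap on mean error but blurs detail (note its larger maximum error in
the full JSON output).

Stage-wise commands (`simulate`, `mask`, `pattern`, `filter`, `fuse`,
`evaluate`, `run`) operate on 16-bit TIFF images, 8-bit PNG masks and
`.str` stream files, so the same workflow can be applied to real
micrographs.

Library use:

```python
from adaptscan import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, adapt_noise=False))
print(result.budget.t_avg)           # 3e-06
print(result.report.snr)             # ~450 against the noise-free truth
```

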