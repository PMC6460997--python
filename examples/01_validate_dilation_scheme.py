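"""Validate dilation-rate schemes against the HDC rules and the coverage oracle.

Stacked dilated convolutions can leave "gridding" holes: input voxels that
never influence the output.  The HDC conditions (pairwise-coprime rates and
the max-distance recurrence staying below the kernel size) guard against
this; the brute-force tap-coverage oracle shows the holes directly.
"""

from ndnseg.netspec import DilationScheme, gridding_coverage, is_hole_free, validate_hdc

for rates in [(1, 2, 5), (2, 2, 2), (1, 2, 9)]:
    scheme = DilationScheme(rates=rates, kernel=3)
    report = validate_hdc(scheme)
    cov = sorted(gridding_coverage(scheme))
    print(f"rates {rates}: valid={report.valid}  max_distances={report.max_distances}")
    print(f"  coverage [{cov[0]}, {cov[-1]}], hole-free={is_hole_free(scheme)}")

# valid=True for (1,2,5): its taps cover every offset in [-8, 8], so the
# 17-voxel receptive field has no blind spots.  (2,2,2) reaches only even
# offsets; (1,2,9) spreads taps further apart than the kernel can bridge.
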