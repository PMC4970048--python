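"""Show that steering is exact: weighted sums of base responses vs. rotated kernels.

For the ridge template T5 the oriented response at an arbitrary angle is compared
against brute-force convolution with the analytically rotated kernel.
"""

import math

import numpy as np
from scipy import ndimage

from graintex import (
    base_responses,
    evaluate_template_kernel,
    get_template,
    oriented_response,
)

rng = np.random.default_rng(0)
image = rng.normal(size=(64, 64))
template = get_template("T5")
sigma = 1.0

base = base_responses(image, template, sigma)
print(f"T5 needs {len(base.responses)} base convolutions; every orientation after")
print("that is a weighted sum (no further convolutions).")
for theta in (0.0, math.pi / 7, 2.3):
    steered = oriented_response(image, template, sigma, theta, base=base).values
    kern = evaluate_template_kernel(template, sigma, theta)
    direct = ndimage.convolve(image, kern.values, mode="mirror")
    h = kern.center[0]
    rel = np.max(np.abs(steered - direct)[h:-h, h:-h]) / np.max(np.abs(direct[h:-h, h:-h]))
    print(f"  theta={theta:.4f}: max interior relative error vs rotated kernel = {rel:.2e}")
print()
print("Errors at machine precision confirm the steering coefficients are exact,")
print("which is what makes omnidirectional filtering at 60 angles affordable.")
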