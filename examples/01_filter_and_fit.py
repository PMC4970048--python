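"""Filter a synthetic grain image at one orientation and fit the Weibull model.

Renders a granular image, computes the steerable edge-template response at 45
degrees, fits the integral-form Weibull law to the interior response histogram and
prints the texture triple with its goodness-of-fit scores.
"""

import math

import numpy as np

from graintex import (
    FitOptions,
    GranularImageSpec,
    fit_wd_mle,
    generate_granular_image,
    get_template,
    oriented_response,
)
from graintex.steerable import kernel_half_width

image = generate_granular_image(GranularImageSpec(seed=7))
template = get_template("T1")
sigma, theta = 1.0, math.pi / 4

resp = oriented_response(image, template, sigma, theta).values
h = kernel_half_width(sigma)
interior = resp[h:-h, h:-h].ravel()

fit = fit_wd_mle(interior, FitOptions())
p = fit.params
print(f"image {image.shape}, template T1, sigma={sigma}, theta=45deg")
print(f"  location mu   = {p.mu:+.5f}   (global reflectance of the response)")
print(f"  scale    beta = {p.beta:.5f}   (response width: local contrast)")
print(f"  shape  lambda = {p.lam:.5f}   (grain size / regularity; 2 = Gaussian)")
print(f"  chi2 = {fit.chi2:.2e}, KLD = {fit.kld:.2e}  (lower = better fit)")
print(f"  converged after {fit.n_iterations} simplex iterations on {fit.n_samples} pixels")
print()
print("A shape well below 2 means the response histogram is heavy-tailed, the")
print("signature of an image built from many stochastically packed fragments.")
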