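"""Exceptions shared across the pipeline."""


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two nonempty bins; no threshold exists."""


class NoForegroundError(ValueError):
    """Tissue mask is empty everywhere; no foreground block can be chosen."""


class NoNucleiError(ValueError):
    """No nuclei were sampled from a slide; shape features are undefined."""


class DegenerateNullError(ValueError):
    """Permutation null has zero variance; the z-score is undefined."""
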