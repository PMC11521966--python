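"""Automated analysis of feto-placental spectral Doppler ultrasound.

A pipeline that classifies the Doppler view of a screen capture (umbilical
artery, middle cerebral artery, aortic isthmus, left ventricular
inflow-outflow), rejects out-of-domain images, delineates the velocity
envelope with its physiological events, and computes clinical Doppler
indices such as the pulsatility index — together with a synthetic
spectrogram simulator that provides exact ground truth for training and
verification.
"""

from .calibration import Calibration

__version__ = "0.1.0"


def __getattr__(name):
    # lazy submodule access: fetaldoppler.synthetic, .pipeline, ...
    import importlib

    if name in (
        "synthetic",
        "preprocessing",
        "gate",
        "views",
        "confidence",
        "delineation",
        "indices",
        "training",
        "pipeline",
        "nn",
    ):
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")


__all__ = ["Calibration", "__version__"]
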