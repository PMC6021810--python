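"""The five classification algorithms sharing a fit/predict contract."""

from .dummy import decode, dummy_code
from .kernels import gaussian_kernel, linear_kernel, puk_kernel
from .knn import KNNClassifier
from .kpls import KernelPLSModel, KPLSDAClassifier, kernel_nipals, kpls_fit
from .lwpls import LWPLSClassifier, lwplsc_predict, similarity_weights
from .pls import PLSDAClassifier, PLSModel, nipals, pls_fit
from .svm import SVMClassifier

ALGORITHMS = ("knn", "svm", "plsda", "kplsda", "lwplsc")

_FACTORIES = {
    "knn": KNNClassifier,
    "svm": SVMClassifier,
    "plsda": PLSDAClassifier,
    "kplsda": KPLSDAClassifier,
    "lwplsc": LWPLSClassifier,
}


def make_classifier(algorithm: str, params: dict | None = None):
    """Instantiate a classifier by name with keyword parameters."""
    if algorithm not in _FACTORIES:
        raise KeyError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return _FACTORIES[algorithm](**(params or {}))


__all__ = [
    "ALGORITHMS",
    "KNNClassifier",
    "SVMClassifier",
    "PLSDAClassifier",
    "KPLSDAClassifier",
    "LWPLSClassifier",
    "PLSModel",
    "KernelPLSModel",
    "make_classifier",
    "dummy_code",
    "decode",
    "gaussian_kernel",
    "linear_kernel",
    "puk_kernel",
    "nipals",
    "kernel_nipals",
    "pls_fit",
    "kpls_fit",
    "lwplsc_predict",
    "similarity_weights",
]
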