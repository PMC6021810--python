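"""Dummy (one-hot) coding of categorical class labels."""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateInputError


def dummy_code(labels):
    """One-hot encode labels.

    Returns ``(Y, class_order)`` where columns follow the sorted unique
    labels and each row sums to 1.  Requires at least two classes.
    """
    labels = np.asarray(labels)
    class_order = sorted(set(labels.tolist()))
    if len(class_order) < 2:
        raise DegenerateInputError("dummy coding needs at least two classes")
    index = {c: j for j, c in enumerate(class_order)}
    Y = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y, class_order


def decode(scores, class_order):
    """Argmax decoding; ties resolve to the first class in ``class_order``."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    idx = np.argmax(scores, axis=1)
    return np.array([class_order[j] for j in idx], dtype=object)
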