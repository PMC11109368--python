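"""Independent O(n²) double-loop references for the spatial statistics."""

import numpy as np

from hextumour.hexgrid import hex_distance


def naive_weights(coords):
    n = len(coords)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and hex_distance(coords[i], coords[j]) == 1:
                w[i, j] = 1.0
    return w


def naive_general_G(coords, x):
    w = naive_weights(coords)
    num = den = 0.0
    for i in range(len(x)):
        for j in range(len(x)):
            if i != j:
                num += w[i, j] * x[i] * x[j]
                den += x[i] * x[j]
    return num / den


def naive_moran_I(coords, x):
    w = naive_weights(coords)
    z = np.asarray(x) - np.mean(x)
    num = sum(w[i, j] * z[i] * z[j]
              for i in range(len(x)) for j in range(len(x)))
    return (len(x) / w.sum()) * num / (z @ z)


def naive_geary_C(coords, x):
    w = naive_weights(coords)
    z = np.asarray(x) - np.mean(x)
    num = sum(w[i, j] * (x[i] - x[j]) ** 2
              for i in range(len(x)) for j in range(len(x)))
    return ((len(x) - 1) / (2 * w.sum())) * num / (z @ z)
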