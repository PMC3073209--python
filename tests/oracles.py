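"""Independent brute-force oracles for the focus measures.

Deliberately written as plain nested loops over explicitly padded
arrays — no shared code with the vectorized implementations they check.
"""

import numpy as np

SOBEL_X = [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]
SOBEL_Y = [[-1, -2, -1], [0, 0, 0], [1, 2, 1]]


def tenengrad_bruteforce(intensity, threshold):
    img = np.asarray(intensity, dtype=float)
    h, w = img.shape
    # symmetric padding == ndimage's "reflect"
    padded = np.pad(img, 1, mode="symmetric")
    total = 0.0
    for y in range(h):
        for x in range(w):
            gx = 0.0
            gy = 0.0
            for dy in range(3):
                for dx in range(3):
                    v = padded[y + dy, x + dx]
                    # correlation-vs-convolution: flip the kernel
                    gx += SOBEL_X[2 - dy][2 - dx] * v
                    gy += SOBEL_Y[2 - dy][2 - dx] * v
            e = gx * gx + gy * gy
            if e > threshold:
                total += e
    return total / (h * w)


def sml_bruteforce(intensity, step, threshold):
    img = np.asarray(intensity, dtype=float)
    h, w = img.shape
    total = 0.0
    count = 0
    for y in range(step, h - step):
        for x in range(step, w - step):
            ml = abs(2 * img[y, x] - img[y, x - step] - img[y, x + step]) \
                + abs(2 * img[y, x] - img[y - step, x] - img[y + step, x])
            count += 1
            if ml >= threshold:
                total += ml
    return total / count
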