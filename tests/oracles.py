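"""Independent scalar re-implementations used as test oracles.

Everything here is written with plain Python loops and ``math`` so it
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math


def mse_oracle(a, b) -> float:
    h, w = len(a), len(a[0])
    s = 0.0
    for i in range(h):
        for j in range(w):
            d = float(b[i][j]) - float(a[i][j])
            s += d * d
    return s / (h * w)


def rmse_oracle(a, b) -> float:
    return math.sqrt(mse_oracle(a, b))


def psnr_oracle(a, b) -> float:
    m = mse_oracle(a, b)
    if m == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0 * 255.0 / m)


def snr_oracle(a, b) -> float:
    sig = err = 0.0
    for i in range(len(a)):
        for j in range(len(a[0])):
            ya = float(a[i][j])
            d = float(b[i][j]) - ya
            sig += ya * ya
            err += d * d
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(sig / err)


def ssim_oracle(a, b) -> float:
    """Global-statistics SSIM with population variance/covariance."""
    c1 = (0.01 * 255.0) ** 2
    c2 = (0.03 * 255.0) ** 2
    h, w = len(a), len(a[0])
    n = h * w
    mu_a = sum(float(a[i][j]) for i in range(h) for j in range(w)) / n
    mu_b = sum(float(b[i][j]) for i in range(h) for j in range(w)) / n
    va = vb = cov = 0.0
    for i in range(h):
        for j in range(w):
            da = float(a[i][j]) - mu_a
            db = float(b[i][j]) - mu_b
            va += da * da
            vb += db * db
            cov += da * db
    va, vb, cov = va / n, vb / n, cov / n
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (va + vb + c2)
    return num / den


def forward_oracle(w_in, b_hidden, w_out, b_out, x, w_rec=None, h_prev=None):
    """Scalar-loop forward pass of the 64-H-64 sigmoid network."""
    n_in = len(w_in)
    n_hid = len(b_hidden)

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    hidden = []
    for j in range(n_hid):
        z = b_hidden[j]
        for i in range(n_in):
            z += float(x[i]) * float(w_in[i][j])
        if w_rec is not None:
            for i in range(n_hid):
                z += float(h_prev[i]) * float(w_rec[i][j])
        hidden.append(sig(z))
    out = []
    for k in range(len(b_out)):
        z = b_out[k]
        for j in range(n_hid):
            z += hidden[j] * float(w_out[j][k])
        out.append(sig(z))
    return hidden, out


def nearest_codeword_oracle(vec, codewords) -> int:
    """Exhaustive argmin with lowest-index tie-break."""
    best, best_d = 0, None
    for k, cw in enumerate(codewords):
        d = sum((float(v) - float(c)) ** 2 for v, c in zip(vec, cw))
        if best_d is None or d < best_d:
            best, best_d = k, d
    return best


def distortion_oracle(vectors, codewords) -> float:
    total = 0.0
    for v in vectors:
        k = nearest_codeword_oracle(v, codewords)
        total += sum((float(a) - float(c)) ** 2
                     for a, c in zip(v, codewords[k]))
    return total / len(vectors)


def lloyd_oracle(vectors, centers, max_iter=200):
    """Plain-loop Lloyd's algorithm (k-means) from given initial centers."""
    centers = [list(map(float, c)) for c in centers]
    dim = len(centers[0])
    for _ in range(max_iter):
        assign = [nearest_codeword_oracle(v, centers) for v in vectors]
        new_centers = []
        for k in range(len(centers)):
            members = [v for v, a in zip(vectors, assign) if a == k]
            if members:
                new_centers.append(
                    [sum(float(m[d]) for m in members) / len(members)
                     for d in range(dim)])
            else:
                new_centers.append(centers[k])
        if all(all(abs(nc - oc) < 1e-15 for nc, oc in zip(n, o))
               for n, o in zip(new_centers, centers)):
            break
        centers = new_centers
    return centers, distortion_oracle(vectors, centers)
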