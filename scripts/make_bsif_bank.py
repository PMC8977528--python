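"""One-time generator of the shipped BSIF filter bank.

Learns 8 zero-mean 7x7 filters by independent component analysis on
mean-removed patches sampled from a seeded synthetic texture corpus
(Gaussian random fields at several correlation lengths), then writes the
bank to ``src/salpinx/data/bsif_7x7_8.csv`` as plain text.  Re-running
reproduces the same file bit for bit.
"""

from pathlib import Path

import numpy as np
from sklearn.decomposition import FastICA

FILTER_SIZE = 7
N_FILTERS = 8
SEED = 20240521


def gaussian_random_field(rng: np.random.Generator, size: int, corr_len: float) -> np.ndarray:
    white = rng.standard_normal((size, size))
    fx = np.fft.fftfreq(size)[:, None]
    fy = np.fft.fftfreq(size)[None, :]
    envelope = np.exp(-2 * (np.pi * corr_len) ** 2 * (fx**2 + fy**2))
    field = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(envelope)).real
    return (field - field.mean()) / field.std()


def main() -> None:
    rng = np.random.default_rng(SEED)
    patches = []
    for corr_len in (1.0, 2.0, 4.0, 8.0):
        for _ in range(8):
            img = gaussian_random_field(rng, 128, corr_len)
            for _ in range(1500):
                i = rng.integers(0, 128 - FILTER_SIZE)
                j = rng.integers(0, 128 - FILTER_SIZE)
                patches.append(img[i : i + FILTER_SIZE, j : j + FILTER_SIZE].ravel())
    x = np.array(patches)
    x -= x.mean(axis=1, keepdims=True)  # remove patch DC

    ica = FastICA(
        n_components=N_FILTERS, whiten="unit-variance", random_state=SEED, max_iter=2000
    )
    ica.fit(x)
    filters = ica.components_.reshape(N_FILTERS, FILTER_SIZE, FILTER_SIZE)
    filters -= filters.mean(axis=(1, 2), keepdims=True)
    filters /= np.linalg.norm(filters, axis=(1, 2), keepdims=True)

    out = Path(__file__).resolve().parents[1] / "src" / "salpinx" / "data" / "bsif_7x7_8.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(out, filters.reshape(N_FILTERS, -1), delimiter=",", fmt="%.10e")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
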