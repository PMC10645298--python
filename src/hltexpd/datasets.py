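"""Bundled reliability/survival datasets and descriptive summaries.

Three small classical lifetime datasets, stored verbatim (full printed
precision, original listing order):

* ``kevlar76`` — 76 fatigue-fracture lifetimes of Kevlar 373/epoxy
  specimens under constant 90% stress until failure (hours).
* ``guinea72`` — survival times of 72 guinea pigs infected with virulent
  tubercle bacilli (time units of the original study).
* ``bearings23`` — millions of revolutions to failure for 23 ball bearings
  on endurance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Dataset", "DescriptiveStats", "load_dataset", "describe", "DATASET_NAMES"]

# values kept as decimal strings, converted once on module import
_KEVLAR76 = """
0.0251 0.0891 0.0886 0.3113 0.8425 0.2501 0.4763 0.5650 0.5671 0.3451
0.8645 0.6566 0.6751 0.6748 0.8375 0.7696 0.6753 0.8391 0.9836 0.8851
0.9120 0.9113 1.0483 1.0773 1.1733 1.0596 1.5733 1.7083 1.2570 1.7263
1.2766 1.2985 1.7630 1.3211 1.3503 1.9316 1.3551 1.4595 1.8808 1.4880
1.5728 1.8881 1.7460 1.8275 1.8375 1.7746 1.8503 1.8878 1.9558 2.2100
2.0408 2.0903 2.1093 2.1330 2.2460 2.0048 2.2878 2.3203 2.3513 2.4951
2.3470 2.9911 2.5260 3.0256 3.2678 3.4045 3.4846 3.7433 3.9143 3.7455
4.8073 5.5295 5.4005 6.5541 5.4435 9.0960
"""

_GUINEA72 = """
0.1 0.96 0.56 0.72 0.44 0.77 0.93 0.33 0.59 0.92 1.00 1.02 1.00 1.07
0.70 0.08 1.08 1.05 1.08 1.12 1.09 1.13 0.74 1.15 1.16 1.20 1.21 1.22
1.22 1.24 1.3 1.34 1.36 1.39 1.44 1.97 1.46 1.59 1.72 1.60 1.68 1.63
1.71 1.63 1.76 1.96 1.83 1.53 1.95 2.02 2.15 2.93 2.16 2.30 2.53 2.31
2.40 2.51 2.22 2.54 2.45 2.54 2.78 2.13 3.61 3.27 3.47 3.42 4.02 4.58
4.32 5.55
"""

_BEARINGS23 = """
17.88 41.52 33.00 42.12 28.92 48.80 51.84 45.60 54.12 67.80 51.96 68.64
55.56 68.88 93.12 68.64 98.64 84.12 128.04 105.12 127.92 105.84 173.40
"""


@dataclass(frozen=True)
class Dataset:
    name: str
    values: np.ndarray
    units: str
    source: str

    @property
    def n(self) -> int:
        return self.values.size


def _parse(block: str) -> np.ndarray:
    vals = np.array([float(tok) for tok in block.split()])
    vals.setflags(write=False)
    return vals


_REGISTRY = {
    "kevlar76": Dataset(
        "kevlar76",
        _parse(_KEVLAR76),
        units="hours",
        source="fatigue-fracture life of Kevlar 373/epoxy at 90% constant stress",
    ),
    "guinea72": Dataset(
        "guinea72",
        _parse(_GUINEA72),
        units="survival time",
        source="guinea pigs infected with virulent tubercle bacilli",
    ),
    "bearings23": Dataset(
        "bearings23",
        _parse(_BEARINGS23),
        units="millions of revolutions",
        source="ball-bearing endurance test, revolutions to failure",
    ),
}

DATASET_NAMES = tuple(sorted(_REGISTRY))


def load_dataset(name: str) -> Dataset:
    """Return a bundled dataset by name (``kevlar76``/``guinea72``/``bearings23``)."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown dataset {name!r}; available: {DATASET_NAMES}") from None


@dataclass(frozen=True)
class DescriptiveStats:
    """Location/spread/shape summary of a sample."""

    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    sd: float
    skewness: float
    kurtosis: float

    def as_record(self) -> dict:
        return {
            "min": self.min, "q1": self.q1, "median": self.median,
            "mean": self.mean, "q3": self.q3, "max": self.max,
            "sd": self.sd, "skewness": self.skewness, "kurtosis": self.kurtosis,
        }


def describe(values) -> DescriptiveStats:
    """Summary statistics under conventional definitions.

    Quartiles use linear interpolation at plotting position (k-1)/(n-1) (the
    numpy/R type-7 default); SD uses the n-1 denominator; skewness and
    (non-excess) kurtosis are central-moment ratios m3/m2^{3/2} and m4/m2^2
    with m_k = mean((x - xbar)^k).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("describe requires at least 4 observations")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    return DescriptiveStats(
        min=float(x.min()),
        q1=float(q1),
        median=float(med),
        mean=float(m),
        q3=float(q3),
        max=float(x.max()),
        sd=float(x.std(ddof=1)),
        skewness=float(m3 / m2**1.5),
        kurtosis=float(m4 / m2**2),
    )
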