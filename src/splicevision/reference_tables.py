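"""Published cross-organism benchmark metrics used as aggregation inputs.

Per-benchmark metric rows (percent, 2-decimal display precision) for the
reference splice-site CNN and the weakest classical baseline (NNSplice),
over six independent benchmarks: human, fish, fly, worm, plant and PVP
(protists + Viridiplantae).  These printed per-benchmark values are inputs;
the package computes their unweighted averages and gaps with
:func:`splicevision.metrics.aggregate_reports`.
"""

from __future__ import annotations

from .metrics import MetricsReport

BENCHMARKS = ("human", "fish", "fly", "worm", "plant", "pvp")

# rows: accuracy, precision, sensitivity, specificity, f1
_CNN_DONOR = {
    "human": (92.7, 90.0, 96.1, 89.4, 93.0),
    "fish": (95.0, 91.6, 99.0, 90.9, 95.1),
    "fly": (94.6, 91.6, 98.3, 91.0, 94.8),
    "worm": (93.9, 91.4, 96.9, 90.9, 94.1),
    "plant": (94.7, 91.8, 98.1, 91.3, 94.9),
    "pvp": (86.0, 82.9, 90.8, 81.2, 86.6),
}
_CNN_ACCEPTOR = {
    "human": (89.5, 86.1, 94.4, 84.7, 90.0),
    "fish": (91.3, 86.0, 98.7, 84.0, 91.9),
    "fly": (90.4, 86.2, 96.4, 84.5, 91.0),
    "worm": (88.8, 86.9, 91.4, 86.2, 89.1),
    "plant": (90.6, 89.1, 92.7, 88.6, 90.8),
    "pvp": (83.5, 83.1, 84.0, 82.9, 83.6),
}
_NNSPLICE_DONOR = {
    "human": (68.4, 62.3, 89.2, 48.5, 73.4),
    "fish": (71.0, 64.3, 90.8, 52.2, 75.3),
    "fly": (71.7, 65.3, 91.4, 52.3, 76.2),
    "worm": (65.8, 61.9, 80.3, 51.7, 69.9),
    "plant": (59.8, 57.2, 78.4, 41.0, 66.2),
    "pvp": (64.8, 60.4, 85.8, 43.6, 70.9),
}

_TABLES = {
    ("cnn", "donor"): _CNN_DONOR,
    ("cnn", "acceptor"): _CNN_ACCEPTOR,
    ("nnsplice", "donor"): _NNSPLICE_DONOR,
}


def benchmark_reports(method: str, site_type: str) -> list[MetricsReport]:
    """Per-benchmark MetricsReport rows for one method and site type."""
    try:
        table = _TABLES[(method, site_type)]
    except KeyError:
        raise KeyError(f"no published table for ({method!r}, {site_type!r}); "
                       f"available: {sorted(_TABLES)}") from None
    return [
        MetricsReport(accuracy=a, precision=p, sensitivity=se,
                      specificity=sp, f1=f1, counts=None,
                      dataset_name=name, site_type=site_type)
        for name, (a, p, se, sp, f1) in table.items()
    ]
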