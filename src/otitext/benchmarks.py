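"""Published benchmark values shipped with the package.

``benchmark_confusion_matrix`` is the 880-record test-set confusion matrix
of the published ensemble free-text otitis classifier this package
replicates methodologically; ``benchmark_model_metrics`` are the published
per-architecture balanced metrics.  They serve as fixed oracles for the
metric arithmetic — feeding the matrix through :mod:`otitext.evaluation`
must reproduce the published accuracy, balanced precision/recall and
balanced F1.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import ConfusionMatrix


def _data_path(name: str):
    return resources.files("otitext").joinpath("data", name)


def benchmark_confusion_matrix() -> ConfusionMatrix:
    """6x6 predicted-by-gold counts of the published ensemble (total 880)."""
    with resources.as_file(_data_path("benchmark_confusion_matrix.tsv")) as p:
        return ConfusionMatrix.load_tsv(p)


def benchmark_model_metrics() -> pd.DataFrame:
    """Published balanced precision/recall, accuracy and balanced F1 per model."""
    with resources.as_file(_data_path("benchmark_model_metrics.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="model")
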