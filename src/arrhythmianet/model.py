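"""Model/Results facade over the pipeline.

`BeatClassificationModel` holds the data and configuration; `fit()` runs the
four blocks (scalogram, network, CoF, classifier) and returns a
`BeatClassificationResults` carrying the evaluation report, fitted
components and a `summary()` table, in the style of statistical modelling
packages.
"""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .preprocess import ECGRecord
from .synth import SynthDataset

__all__ = ["BeatClassificationModel", "BeatClassificationResults"]


class BeatClassificationModel:
    """Arrhythmia beat classifier built from labelled ECG data.

    Parameters
    ----------
    data : SynthDataset or list of ECGRecord
        Labelled beats, or records to be segmented into beats.
    config : PipelineConfig, optional
        Full pipeline configuration; keyword overrides are applied on top
        (e.g. ``seed=3``, ``cof_k=10``).
    """

    def __init__(self, data, config: PipelineConfig | None = None, **overrides):
        self.data = data
        cfg = config if config is not None else PipelineConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        self.config = cfg

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float, label_col: str = "label",
                       **kwargs) -> "BeatClassificationModel":
        """Build from a frame with one beat per row (label column + samples)."""
        sample_cols = [c for c in df.columns if c != label_col]
        records = [
            ECGRecord(row[sample_cols].to_numpy(dtype=float), fs=fs,
                      record_id=f"row{i}", label=str(row[label_col]))
            for i, (_, row) in enumerate(df.iterrows(), start=1)
        ]
        return cls(records, **kwargs)

    def fit(self, outdir=None) -> "BeatClassificationResults":
        result = run_pipeline(self.data, self.config, outdir=outdir)
        return BeatClassificationResults(self, result)


class BeatClassificationResults:
    """Fitted pipeline with its held-out evaluation."""

    def __init__(self, model: BeatClassificationModel, result: PipelineResult):
        self.model = model
        self._result = result
        self.report = result.report
        self.loss_trace = result.loss_trace
        self.network = result.network
        self.vocabulary = result.vocabulary
        self.classifier = result.classifier
        self.classes = result.classes
        self.manifest = result.manifest

    @property
    def confusion(self) -> pd.DataFrame:
        return self.report.confusion.to_frame()

    def summary(self) -> str:
        r = self.report
        row = r.summary_row()
        buf = io.StringIO()
        buf.write("Beat classification results\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"{'Classes':<28}{len(self.classes):>18}\n")
        buf.write(f"{'Evaluated beats':<28}{r.confusion.total:>18}\n")
        buf.write(f"{'Vocabulary size k':<28}{self.vocabulary.k:>18}\n")
        buf.write(f"{'Attention gate':<28}"
                  f"{'on' if self.manifest['attention_enabled'] else 'off':>18}\n")
        buf.write("-" * 46 + "\n")
        for key in ("Accuracy", "Sensitivity", "Specificity", "Error"):
            buf.write(f"{key + ' (%)':<28}{row[key]:>18.2f}\n")
        buf.write(f"{'F1-score':<28}{row['F1-Score']:>18.3f}\n")
        kappa_key = "Cohen's Kappa"
        buf.write(f"{'Cohen kappa':<28}{row[kappa_key]:>18.3f}\n")
        buf.write("=" * 46 + "\n")
        return buf.getvalue()

    def plot_loss(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.loss_trace) + 1), self.loss_trace, "o-")
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean training loss")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
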