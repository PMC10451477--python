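"""Synthetic gene-expression matrices shaped like the Lung Harvard 2 study.

The real study data is a 12,533-gene x 181-subject intensity matrix with a
strong class imbalance (150 adenocarcinoma vs 31 mesothelioma subjects) and
non-negative, heavy-tailed intensities.  That dataset is not redistributable,
so everything downstream of this module is exercised on a generated stand-in:
log-normal baseline intensities per gene, with a designated subset of
"informative" genes whose log-mean is shifted in the mesothelioma class.

The on-disk dialect is a delimited text matrix, one row per gene, whose final
row carries numeric class codes (1 = Adeno, 2 = Meso).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, MatrixFormatError

ADENO = "Adeno"
MESO = "Meso"
LABEL_CODES = {ADENO: 1, MESO: 2}
CODE_LABELS = {1: ADENO, 2: MESO}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic expression-matrix generator.

    Defaults mirror the study conditions: 12,533 genes, 150 Adeno and 31 Meso
    subjects.  ``effect_size`` is a log-scale mean shift applied to
    ``n_informative_genes`` genes in the Meso class; ``noise_sd`` is the
    per-observation log-scale noise around each gene's baseline.
    """

    n_genes: int = 12_533
    n_adeno: int = 150
    n_meso: int = 31
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.0
    n_informative_genes: int = 300
    effect_size: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_adeno <= 0 or self.n_meso <= 0:
            raise InvalidConfigError("gene and subject counts must be positive")
        if self.n_informative_genes < 0 or self.n_informative_genes > self.n_genes:
            raise InvalidConfigError(
                "n_informative_genes must lie in [0, n_genes]"
            )
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be >= 0")
        if self.baseline_log_sd <= 0 or self.noise_sd <= 0:
            raise InvalidConfigError("standard deviations must be > 0")


@dataclass
class ExpressionMatrix:
    """A genes x subjects intensity matrix with per-subject class labels."""

    values: np.ndarray
    labels: np.ndarray
    gene_ids: np.ndarray | None = None
    subject_ids: np.ndarray | None = None
    informative_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise InvalidConfigError("values must be a 2-D genes x subjects matrix")
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("intensities must be finite")
        if np.any(self.values < 0):
            raise InvalidConfigError("intensities must be non-negative")
        if self.labels.shape[0] != self.values.shape[1]:
            raise InvalidConfigError(
                f"label count {self.labels.shape[0]} does not match "
                f"subject count {self.values.shape[1]}"
            )
        unknown = set(self.labels) - set(LABEL_CODES)
        if unknown:
            raise InvalidConfigError(f"unknown class labels: {sorted(unknown)}")
        if self.gene_ids is None:
            self.gene_ids = np.array(
                [f"g{i}" for i in range(self.values.shape[0])], dtype=object
            )
        if self.subject_ids is None:
            self.subject_ids = np.array(
                [f"s{j}" for j in range(self.values.shape[1])], dtype=object
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def label_codes(self) -> np.ndarray:
        """Labels as integer codes (Adeno=1, Meso=2)."""
        return np.array([LABEL_CODES[l] for l in self.labels], dtype=int)

    def require_both_classes(self) -> None:
        present = set(self.labels)
        if present != {ADENO, MESO}:
            raise InvalidConfigError(
                f"both classes required for training, found only {sorted(present)}"
            )


def generate_dataset(config: SynthConfig) -> ExpressionMatrix:
    """Draw a synthetic expression matrix from ``config``.

    Intensities are log-normal: gene g has baseline log-intensity
    b_g ~ N(baseline_log_mean, baseline_log_sd²); each observation adds
    N(0, noise_sd²) log-scale noise, and informative genes add
    ``effect_size`` to the log-mean in Meso columns.  Pure function of the
    config, including its seed.
    """
    rng = np.random.default_rng(config.seed)
    n_subjects = config.n_adeno + config.n_meso
    labels = np.array(
        [ADENO] * config.n_adeno + [MESO] * config.n_meso, dtype=object
    )

    baseline = rng.normal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    informative = np.zeros(config.n_genes, dtype=bool)
    if config.n_informative_genes:
        idx = rng.choice(
            config.n_genes, size=config.n_informative_genes, replace=False
        )
        informative[idx] = True

    log_values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_subjects)
    )
    if config.effect_size:
        meso_cols = labels == MESO
        log_values[np.ix_(informative, meso_cols)] += config.effect_size

    return ExpressionMatrix(
        values=np.exp(log_values),
        labels=labels,
        informative_mask=informative,
    )


def write_matrix(
    data: ExpressionMatrix, destination: str | Path, delimiter: str = "\t"
) -> None:
    """Write ``data`` as delimited text with a trailing label row.

    Values are written with 17 significant digits so a read/write round trip
    is exact; the label row holds the integer class codes.
    """
    if data.labels.shape[0] != data.values.shape[1]:
        raise InvalidConfigError("label/subject count mismatch")
    destination = Path(destination)
    try:
        with destination.open("w") as fh:
            for row in data.values:
                fh.write(delimiter.join(format(v, ".17g") for v in row))
                fh.write("\n")
            fh.write(delimiter.join(str(c) for c in data.label_codes()))
            fh.write("\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise MatrixFormatError(f"cannot write matrix to {destination}: {exc}") from exc


def read_matrix(source: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited matrix whose final row is the class-code label row."""
    source = Path(source)
    try:
        text = source.read_text()
    except OSError as exc:
        raise MatrixFormatError(f"cannot read matrix from {source}: {exc}") from exc

    lines = text.splitlines()
    if len(lines) < 2:
        raise MatrixFormatError(
            f"{source}: need at least one gene row and a label row, "
            f"got {len(lines)} line(s)"
        )

    rows: list[list[float]] = []
    width: int | None = None
    for lineno, line in enumerate(lines, start=1):
        try:
            row = [float(tok) for tok in line.split(delimiter)]
        except ValueError as exc:
            raise MatrixFormatError(f"{source}: line {lineno}: {exc}") from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise MatrixFormatError(
                f"{source}: line {lineno}: expected {width} columns, got {len(row)}"
            )
        rows.append(row)

    label_row = rows[-1]
    labels = []
    for j, code in enumerate(label_row):
        if code not in (1.0, 2.0):
            raise MatrixFormatError(
                f"{source}: line {len(lines)}: unknown class code {code!r} "
                f"in column {j + 1} (expected 1=Adeno or 2=Meso)"
            )
        labels.append(CODE_LABELS[int(code)])

    values = np.asarray(rows[:-1], dtype=float)
    if np.any(values < 0):
        bad = int(np.argwhere(np.min(values, axis=1) < 0)[0, 0]) + 1
        raise MatrixFormatError(f"{source}: line {bad}: negative intensity")
    return ExpressionMatrix(values=values, labels=np.array(labels, dtype=object))


def to_frame(data: ExpressionMatrix) -> pd.DataFrame:
    """Convenience view: genes x subjects DataFrame with labelled columns."""
    return pd.DataFrame(data.values, index=data.gene_ids, columns=data.subject_ids)
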