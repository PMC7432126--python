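"""Shared table readers/writers and run configuration.

TSV (tab-separated, UTF-8, "." decimal) is the canonical tabular dialect.
Readers tolerate the unicode minus sign used by some typeset tables; writers
prepend a comment header carrying the config hash and seed so reruns are
traceable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from .composite import ScoreMatrix

__all__ = [
    "RunConfig",
    "read_config",
    "read_table",
    "read_score_table",
    "write_table",
]

_UNICODE_MINUS = "−"


@dataclass
class RunConfig:
    """Flat key-value run configuration with validated defaults."""

    floor_a: float = 0.9
    orientations: str = ""          # comma-separated, empty = all benefit
    grid_spacing: float = 2.0
    grid_margin: float = 4.0
    alpha: float = 0.3
    drop_sigma: float = 0.01
    max_components: int = 10
    scramble_permutations: int = 20
    scramble_seed: int = 1729
    toxicity_threshold: float = 10.0
    bcf_threshold: float = 100.0
    biodeg_gain_threshold: float = 15.0
    seed: int = 20200723
    out_dir: str = "paedeg_out"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.floor_a < 1.0:
            raise ValueError("floor_a must be in (0, 1)")
        if self.grid_spacing <= 0 or self.grid_margin <= 0:
            raise ValueError("grid spacing/margin must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")

    def digest(self) -> str:
        # out_dir is deployment detail, not part of the scientific config
        payload = repr(sorted((k, v) for k, v in asdict(self).items()
                              if k != "out_dir"))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` text config file."""
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extras"}
    kwargs: dict = {}
    extras: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in known:
            typ = type(getattr(RunConfig(), key))
            kwargs[key] = typ(val) if typ is not str else val
        else:
            extras[key] = val
    return RunConfig(**kwargs, extras=extras)


def read_table(path, index_col: int | str | None = 0) -> pd.DataFrame:
    """Read a TSV table, tolerating unicode minus and comment headers."""
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    text = text.replace(_UNICODE_MINUS, "-")
    from io import StringIO
    try:
        df = pd.read_csv(StringIO(text), sep="\t", comment="#",
                         index_col=index_col)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    return df


def read_score_table(path, orientations=None) -> ScoreMatrix:
    """Read a compounds x endpoints score TSV into a :class:`ScoreMatrix`.

    First column: compound id; header row: endpoint ids.  Non-numeric
    columns (annotations such as a train/test role) are ignored.
    """
    df = read_table(path, index_col=0)
    numeric_cols = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        ok = coerced.notna()
        if ok.all():
            numeric_cols[col] = coerced
        elif ok.any():
            bad = df.index[~ok][0]
            raise ValueError(
                f"{path}: malformed value {df[col][~ok].iloc[0]!r} in "
                f"column {col!r}, row {bad!r}")
        # all-NaN after coercion: an annotation column, ignored
    if not numeric_cols:
        raise ValueError(f"{path}: no numeric endpoint columns found")
    num = pd.DataFrame(numeric_cols, index=df.index)
    if num.index.duplicated().any():
        dup = num.index[num.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate compound id {dup!r}")
    if num.isna().any().any():
        bad = num.index[num.isna().any(axis=1)][0]
        raise ValueError(f"{path}: malformed numeric value in row {bad!r}")
    return ScoreMatrix.from_frame(num, orientation=orientations)


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None,
                index: bool = True, float_format: str = "%.6g") -> None:
    """Write a TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ""
    if config is not None:
        header = f"# paedeg config={config.digest()} seed={config.seed}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)
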