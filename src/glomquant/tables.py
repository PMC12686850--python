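"""Loaders for the published per-dataset reference tables.

The study's raw image stacks are not publicly deposited, but its
per-dataset summary tables are printed in full. They are shipped here
as small CSV fixtures (clearly marked paper-derived) so the statistics
layer and the literature calculators can be exercised on the exact
in-paper inputs. Group-level rows (medians of the four per-dataset
medians, IQRs) are deliberately *not* stored: they are recomputed by
:mod:`glomquant.stats`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_counts_sizes", "load_moments", "load_shape", "AGE_GROUPS"]

AGE_GROUPS = ("PD14", "PD21", "PD56")


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("glomquant.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def load_counts_sizes() -> pd.DataFrame:
    """Per-dataset glomerular counts, total/median volumes, diameters."""
    return _load("table2_counts_sizes.csv")


def load_moments() -> pd.DataFrame:
    """Per-dataset skewness and excess kurtosis of effective diameters."""
    return _load("table3_moments.csv")


def load_shape() -> pd.DataFrame:
    """Per-dataset quartiles of ALR x/z, y/z and sphericity."""
    return _load("table4_shape.csv")


def group_values(df: pd.DataFrame, column: str) -> dict[str, list[float]]:
    """Column values per age group, in table order."""
    return {
        g: df.loc[df["age_group"] == g, column].tolist() for g in AGE_GROUPS
    }
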