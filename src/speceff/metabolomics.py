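"""Untargeted-metabolomics feature-table preprocessing.

The filter chain applied to LC-MS feature tables before differential
analysis, in this fixed order:

1. ``filter_missing`` — drop features whose zero (missing) fraction exceeds
   50% per group;
2. ``impute_half_min`` — replace remaining zeros by half the feature's
   minimum positive value;
3. ``filter_score`` — drop features whose vendor identification score
   (0-60 points) is below 36.

Positive- and negative-mode tables are merged feature-wise beforehand.  The
identification score is consumed as input, never computed here.  Every filter
returns a log with conserved counts (in = removed + retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureTable:
    """Samples x features intensity table with group labels and id scores.

    Zeros in ``intensities`` denote missing measurements (the usual vendor
    export convention).  ``groups`` labels each sample; ``id_score`` and
    ``ion_mode`` annotate each feature.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    id_score: pd.Series
    ion_mode: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.groups.index) != list(self.intensities.index):
            raise ValueError("groups must be indexed by the table's sample ids")
        if list(self.id_score.index) != list(self.intensities.columns):
            raise ValueError("id_score must be indexed by the table's feature ids")
        scores = self.id_score.dropna()
        if ((scores < 0) | (scores > 60)).any():
            raise ValueError("identification scores must lie in [0, 60]")
        if self.ion_mode is None:
            self.ion_mode = pd.Series("unknown", index=self.intensities.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    def _subset(self, keep: pd.Index | list) -> "FeatureTable":
        return FeatureTable(
            intensities=self.intensities[keep].copy(),
            groups=self.groups.copy(),
            id_score=self.id_score[keep].copy(),
            ion_mode=self.ion_mode[keep].copy(),
        )


@dataclass
class FilterLog:
    """Audit record for one filter rule: in = removed + retained."""

    rule: str
    parameters: dict
    n_in: int
    n_removed: int
    n_retained: int
    removed_features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_in != self.n_removed + self.n_retained:
            raise ValueError("filter log counts are not conserved")

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "parameters": self.parameters,
            "n_in": self.n_in,
            "n_removed": self.n_removed,
            "n_retained": self.n_retained,
            "removed_features": list(self.removed_features),
        }


def filter_missing(
    table: FeatureTable,
    max_fraction: float = 0.5,
    quantifier: str = "all_groups",
) -> tuple[FeatureTable, FilterLog]:
    """Remove features with too many zeros per group.

    A feature's zero-fraction is evaluated within each sample group; with the
    default ``quantifier="all_groups"`` a feature is removed only when the
    fraction strictly exceeds ``max_fraction`` in *every* group (a feature
    well measured in one group survives).  ``quantifier="any_group"`` removes
    on exceedance in any single group.  The boundary is strict: exactly 50%
    zeros is retained.
    """
    if quantifier not in ("all_groups", "any_group"):
        raise ValueError(f"unknown quantifier {quantifier!r}")
    zero = table.intensities == 0
    frac = zero.groupby(table.groups, observed=True).mean()  # groups x features
    exceeds = frac > max_fraction
    removed_mask = exceeds.all(axis=0) if quantifier == "all_groups" else exceeds.any(axis=0)
    keep = [f for f in table.feature_ids if not removed_mask[f]]
    removed = [f for f in table.feature_ids if removed_mask[f]]
    log = FilterLog(
        rule="missing_value_filter",
        parameters={"max_fraction": max_fraction, "quantifier": quantifier},
        n_in=len(table.feature_ids),
        n_removed=len(removed),
        n_retained=len(keep),
        removed_features=removed,
    )
    return table._subset(keep), log


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace zeros by half of the feature's minimum positive value."""
    values = table.intensities.to_numpy(dtype=float).copy()
    for j, fid in enumerate(table.feature_ids):
        col = values[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            if np.any(col == 0):
                raise ValueError(
                    f"feature {fid!r} has no positive value to impute from; "
                    "apply filter_missing first"
                )
            continue
        col[col == 0] = positive.min() / 2.0
    out = table._subset(table.feature_ids)
    out.intensities = pd.DataFrame(
        values, index=table.intensities.index, columns=table.intensities.columns
    )
    return out


def filter_score(
    table: FeatureTable, min_score: float = 36.0
) -> tuple[FeatureTable, FilterLog]:
    """Keep features whose identification score is at least ``min_score``.

    The boundary is inclusive: a score of exactly 36 is retained.  Features
    with no score are removed and listed in the log.
    """
    scores = table.id_score
    unscored = [f for f in table.feature_ids if pd.isna(scores[f])]
    keep = [f for f in table.feature_ids if not pd.isna(scores[f]) and scores[f] >= min_score]
    removed = [f for f in table.feature_ids if f not in set(keep)]
    log = FilterLog(
        rule="identification_score_filter",
        parameters={"min_score": min_score, "unscored_removed": unscored},
        n_in=len(table.feature_ids),
        n_removed=len(removed),
        n_retained=len(keep),
        removed_features=removed,
    )
    return table._subset(keep), log


def merge_ion_modes(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    """Concatenate positive- and negative-mode tables feature-wise.

    Sample sets must agree; the negative table is aligned to the positive
    table's sample order.  Feature ids are suffixed by mode so duplicates
    across modes stay distinct.
    """
    pos_samples, neg_samples = set(pos.sample_ids), set(neg.sample_ids)
    if pos_samples != neg_samples:
        only_pos = sorted(pos_samples - neg_samples)
        only_neg = sorted(neg_samples - pos_samples)
        raise ValueError(
            f"sample sets differ between ion modes: only in pos {only_pos}, "
            f"only in neg {only_neg}"
        )
    neg_int = neg.intensities.loc[pos.sample_ids]

    def _suffix(df_cols, mode):
        return [f"{c}_{mode}" for c in df_cols]

    pos_ids = _suffix(pos.feature_ids, "pos")
    neg_ids = _suffix(neg.feature_ids, "neg")
    intensities = pd.concat(
        [
            pos.intensities.set_axis(pos_ids, axis=1),
            neg_int.set_axis(neg_ids, axis=1),
        ],
        axis=1,
    )
    id_score = pd.concat(
        [pos.id_score.set_axis(pos_ids), neg.id_score.set_axis(neg_ids)]
    )
    ion_mode = pd.Series(
        ["pos"] * len(pos_ids) + ["neg"] * len(neg_ids), index=pos_ids + neg_ids
    )
    return FeatureTable(
        intensities=intensities,
        groups=pos.groups.copy(),
        id_score=id_score,
        ion_mode=ion_mode,
    )


def write_feature_table_csv(table: FeatureTable, path) -> None:
    """Write a feature table as wide CSV: features as rows, samples as columns.

    The header is two rows (group labels, then sample ids); ``id_score`` and
    ``ion_mode`` are appended as trailing per-feature columns.
    """
    wide = table.intensities.T
    wide.columns = pd.MultiIndex.from_arrays(
        [table.groups.reindex(wide.columns), wide.columns],
        names=["group", "sample_id"],
    )
    wide[("annotation", "id_score")] = table.id_score
    wide[("annotation", "ion_mode")] = table.ion_mode
    wide.to_csv(path, index_label="feature_id")


def read_feature_table_csv(path) -> FeatureTable:
    wide = pd.read_csv(path, header=[0, 1], index_col=0)
    score = wide.pop(("annotation", "id_score")).astype(float)
    ion = wide.pop(("annotation", "ion_mode")).astype(str)
    groups = pd.Series(
        [g for g, _ in wide.columns], index=[s for _, s in wide.columns]
    )
    intensities = wide.T.astype(float)
    intensities.index = groups.index
    intensities.columns.name = None
    for s in (score, ion):
        s.index.name = None
    return FeatureTable(
        intensities=intensities, groups=groups, id_score=score, ion_mode=ion
    )


def preprocess(
    table: FeatureTable,
    max_missing_fraction: float = 0.5,
    min_score: float = 36.0,
    quantifier: str = "all_groups",
) -> tuple[FeatureTable, list[FilterLog]]:
    """Run the full filter chain in its fixed order; return table + logs."""
    filtered, log1 = filter_missing(table, max_missing_fraction, quantifier)
    imputed = impute_half_min(filtered)
    scored, log2 = filter_score(imputed, min_score)
    return scored, [log1, log2]
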