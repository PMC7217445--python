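"""Long-format choice data: container, validation, opt-out filtering, CSV I/O.

The canonical interchange schema is a CSV with columns
``respondent_id, situation_id, alternative_id, chosen, is_opt_out`` followed
by one effect-coded column per attribute (+1/-1; 0 only on opt-out rows).
Each (respondent, situation) group is one choice situation with exactly one
chosen alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Attribute
from .exceptions import InvalidInputError, SchemaError

logger = logging.getLogger(__name__)

ID_COLUMNS = ["respondent_id", "situation_id", "alternative_id", "chosen", "is_opt_out"]


@dataclass
class ChoiceDataset:
    """Respondent x situation x alternative records with effect codes.

    ``df`` holds one row per alternative offered; ``attributes`` names and
    orders the code columns.  Opt-out rows carry all-zero codes and are
    flagged ``is_opt_out``.
    """

    attributes: list
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        names = [a.name for a in self.attributes]
        missing = [c for c in ID_COLUMNS + names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"dataset frame is missing columns: {missing}")
        self.df = self.df[ID_COLUMNS + names].reset_index(drop=True)
        self.df = self.df.astype(
            {c: int for c in ["alternative_id", "chosen", "is_opt_out", *names]},
            errors="ignore",
        )

    @property
    def attribute_names(self):
        return [a.name for a in self.attributes]

    @property
    def n_respondents(self):
        return self.df["respondent_id"].nunique()

    @property
    def n_situations(self):
        return len(self.df.groupby(["respondent_id", "situation_id"], sort=False))

    def codes(self):
        return self.df[self.attribute_names].to_numpy(dtype=float)

    def copy(self):
        return ChoiceDataset(list(self.attributes), self.df.copy())

    def __eq__(self, other):
        if not isinstance(other, ChoiceDataset):
            return NotImplemented
        return self.attributes == other.attributes and self.df.equals(other.df)


def validate(dataset):
    """Report invariant violations; an empty list means a well-formed dataset.

    Checks per situation: distinct alternative positions starting at 1 and
    exactly one chosen row; per row: codes in {-1,+1} (0 only for opt-outs).
    """
    problems = []
    names = dataset.attribute_names
    df = dataset.df
    codes = df[names].to_numpy()
    opt = df["is_opt_out"].to_numpy(dtype=bool)
    bad_design = (~np.isin(codes, (-1, 1))).any(axis=1) & ~opt
    for idx in np.flatnonzero(bad_design):
        row = df.iloc[idx]
        problems.append(
            f"respondent {row.respondent_id} situation {row.situation_id} "
            f"alternative {row.alternative_id}: codes must be +1/-1"
        )
    bad_opt = (codes != 0).any(axis=1) & opt
    for idx in np.flatnonzero(bad_opt):
        row = df.iloc[idx]
        problems.append(
            f"respondent {row.respondent_id} situation {row.situation_id}: "
            "opt-out row carries attribute codes"
        )
    for (resp, sit), grp in df.groupby(["respondent_id", "situation_id"], sort=False):
        alts = grp["alternative_id"].tolist()
        if len(set(alts)) != len(alts):
            problems.append(f"respondent {resp} situation {sit}: duplicate alternative ids")
        elif min(alts) != 1:
            problems.append(f"respondent {resp} situation {sit}: alternatives must start at 1")
        n_chosen = int(grp["chosen"].sum())
        if n_chosen != 1:
            problems.append(
                f"respondent {resp} situation {sit}: {n_chosen} alternatives chosen"
            )
    return problems


def drop_opt_outs(dataset):
    """Remove opt-out alternatives the way the study's analysis did.

    Situations whose *chosen* alternative is the opt-out are removed
    entirely; remaining situations lose their opt-out row but keep their
    designed alternatives (and their positions).  Returns the filtered
    dataset and a dict of removal counts.  Idempotent.
    """
    df = dataset.df
    key = ["respondent_id", "situation_id"]
    chose_opt = df[(df["chosen"] == 1) & (df["is_opt_out"] == 1)][key]
    removed_situations = len(chose_opt)
    if removed_situations:
        mask = df.merge(chose_opt.assign(_drop=1), on=key, how="left")["_drop"].notna()
        df = df[~mask.to_numpy()]
    kept = df[df["is_opt_out"] == 0].reset_index(drop=True)
    out = ChoiceDataset(list(dataset.attributes), kept)
    counts = {
        "situations_removed": removed_situations,
        "situations_retained": out.n_situations,
        "rows_removed": len(dataset.df) - len(kept),
    }
    if out.n_situations == 0:
        logger.warning("all situations chose the opt-out; filtered dataset is empty")
    logger.info(
        "opt-out filtering removed %d situations, retained %d",
        removed_situations,
        counts["situations_retained"],
    )
    return out, counts


def write_choice_csv(dataset, path):
    dataset.df.to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(dataset.df), path)


def read_choice_csv(path, attributes=None):
    """Read the canonical choice CSV.

    When ``attributes`` is omitted, every non-ID column is taken as an
    attribute with default level labels.
    """
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if attributes is None:
        attributes = [Attribute(name=c) for c in df.columns if c not in ID_COLUMNS]
    names = [a.name for a in attributes]
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing attribute columns {missing}")
    codes = df[names].to_numpy()
    bad = ~np.isin(codes, (-1, 0, 1))
    if bad.any():
        rows = (np.flatnonzero(bad.any(axis=1)) + 2).tolist()  # 1-based + header
        raise SchemaError(f"{path}: non -1/0/+1 attribute codes at file rows {rows[:10]}")
    logger.info("read %d rows from %s", len(df), path)
    return ChoiceDataset(list(attributes), df)
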