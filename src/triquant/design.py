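"""Five-level, three-factor calibration design (25 mixtures) and its
training/validation partition.

The generator uses a cyclic difference construction: a fixed base
sequence of 25 level indices whose lag-1 and lag-2 ordered pairs each
enumerate all 25 level combinations exactly once.  The three factor
columns are the base sequence and its cyclic shifts by one and two rows,
so every factor column carries each level exactly five times and every
ordered level pair of any two factors occurs exactly once.

The published 25-mixture layout this package targets (OLM 15-25, AML 3-7,
HCT 10-15 ug/mL) ships as a fixture CSV; its row order follows a
different (unstated) generator phase, so comparisons against it should
use balance properties and row sets, not row order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASE_SEQUENCE",
    "DEFAULT_LEVELS",
    "LAB_MIXTURES",
    "DesignMatrix",
    "build_design",
    "split",
    "table1_design",
    "level_frequencies",
    "ordered_pair_counts",
]

#: Canonical base sequence over levels 0..4: its lag-1 and lag-2 ordered
#: pairs each cover all 25 combinations exactly once (verified in tests).
BASE_SEQUENCE = (0, 0, 1, 0, 2, 2, 0, 3, 3, 1, 2, 1, 4, 0,
                 4, 4, 2, 3, 2, 4, 1, 1, 3, 4, 3)

N_RUNS = 25
N_LEVELS = 5

#: Concentration levels (ug/mL) matching the tablet ratio OLM:AML:HCT of
#: roughly 4:1:2.5 around the assay working point (20, 5, 12.5).
DEFAULT_LEVELS: dict[str, tuple[float, ...]] = {
    "OLM": (15.0, 17.5, 20.0, 22.5, 25.0),
    "AML": (3.0, 4.0, 5.0, 6.0, 7.0),
    "HCT": (10.0, 11.25, 12.5, 13.75, 15.0),
}

#: The nine specificity-study mixtures (AML, OLM, HCT in ug/mL).  All
#: nine are rows of the published 25-mixture design; the default split
#: scheme marks them as the validation set.
LAB_MIXTURES: tuple[dict[str, float], ...] = tuple(
    {"AML": a, "OLM": o, "HCT": h}
    for a, o, h in [
        (7, 25, 10), (5, 15, 13.75), (6, 15, 10),
        (7, 15, 11.25), (7, 17.5, 12.5), (5, 17.5, 10),
        (6, 17.5, 15), (5, 20, 12.5), (6, 20, 13.75),
    ]
)

TRAINING = "training"
VALIDATION = "validation"


@dataclass
class DesignMatrix:
    """A 25-run, three-factor, five-level concentration layout.

    ``codes`` holds the per-run level index (0..4) for each factor;
    ``concentrations`` the mapped ug/mL values (one column per factor);
    ``partition`` tags each run as training or validation once
    :func:`split` has been applied.
    """

    codes: np.ndarray                       # (25, n_factors) ints
    levels: dict[str, tuple[float, ...]]    # factor -> 5 level values
    concentrations: pd.DataFrame            # (25, n_factors) floats
    partition: np.ndarray | None = None     # (25,) of {training, validation}

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.concentrations.columns)

    @property
    def n_runs(self) -> int:
        return int(self.codes.shape[0])

    def subset(self, tag: str) -> pd.DataFrame:
        if self.partition is None:
            raise ValueError("design has not been split yet")
        return self.concentrations[self.partition == tag]

    def to_csv(self, path: str | Path) -> None:
        df = self.concentrations.copy()
        df.insert(0, "mix_no", np.arange(1, self.n_runs + 1))
        df["partition"] = self.partition if self.partition is not None else ""
        df.to_csv(path, index=False)


def build_design(levels: Mapping[str, Sequence[float]] | None = None) -> DesignMatrix:
    """Cyclic five-level multifactor design over 25 runs.

    ``levels`` maps each factor name to its five concentration levels
    (ug/mL); level index j is the j-th entry as given.  Repeated values
    are allowed (a constant factor is the degenerate case) but each factor
    must supply exactly five entries.
    """
    lv = {k: tuple(float(x) for x in v)
          for k, v in (levels or DEFAULT_LEVELS).items()}
    if not lv:
        raise ValueError("at least one factor is required")
    for name, vals in lv.items():
        if len(vals) != N_LEVELS:
            raise ValueError(
                f"factor {name!r} must have exactly {N_LEVELS} levels, "
                f"got {len(vals)}"
            )
    base = np.array(BASE_SEQUENCE, dtype=int)
    codes = np.column_stack([np.roll(base, -j) for j in range(len(lv))])
    conc = pd.DataFrame(
        {name: np.asarray(vals)[codes[:, j]]
         for j, (name, vals) in enumerate(lv.items())}
    )
    return DesignMatrix(codes=codes, levels=lv, concentrations=conc)


def table1_design() -> DesignMatrix:
    """The published 25-mixture layout, loaded from the packaged fixture."""
    with resources.files("triquant.data").joinpath("design_25_mixtures.csv").open() as fh:
        df = pd.read_csv(fh)
    conc = df[["OLM", "AML", "HCT"]].astype(float).reset_index(drop=True)
    levels = {c: tuple(sorted(conc[c].unique())) for c in conc.columns}
    codes = np.column_stack([
        np.searchsorted(np.asarray(levels[c]), conc[c].to_numpy())
        for c in conc.columns
    ])
    return DesignMatrix(codes=codes, levels=levels, concentrations=conc)


def split(design: DesignMatrix, n_train: int = 16,
          scheme: str = "lab-mixtures") -> DesignMatrix:
    """Deterministic training/validation partition.

    Schemes
    -------
    ``lab-mixtures``
        Marks as validation every design row whose composition matches
        one of the nine specificity-study mixtures.  Falls back to
        ``stride`` when the matches do not account for exactly the
        required number of validation rows (e.g. for custom level sets).
    ``stride``
        Validation rows are taken every third row starting at row index
        2, wrapping around the 25 rows until the quota is filled.
    """
    n = design.n_runs
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    n_val = n - n_train

    val_idx: list[int] | None = None
    if scheme == "lab-mixtures":
        matches = []
        conc = design.concentrations
        for i in range(n):
            row = conc.iloc[i].to_dict()
            for mix in LAB_MIXTURES:
                if all(abs(row.get(k, np.nan) - v) < 1e-9 for k, v in mix.items()):
                    matches.append(i)
                    break
        if len(matches) == n_val:
            val_idx = matches
        # otherwise fall through to the stride scheme
    elif scheme != "stride":
        raise ValueError(f"unknown split scheme {scheme!r}")

    if val_idx is None:
        val_idx = []
        i = 2
        while len(val_idx) < n_val:
            if i % n not in val_idx:
                val_idx.append(i % n)
            i += 3
    partition = np.full(n, TRAINING, dtype=object)
    partition[np.asarray(val_idx, dtype=int)] = VALIDATION
    return replace(design, partition=partition)


# -- balance diagnostics --------------------------------------------------

def level_frequencies(design: DesignMatrix) -> pd.DataFrame:
    """Occurrences of each level index per factor column."""
    out = {}
    for j, name in enumerate(design.factors):
        out[name] = np.bincount(design.codes[:, j], minlength=N_LEVELS)
    return pd.DataFrame(out, index=range(N_LEVELS))


def ordered_pair_counts(design: DesignMatrix, factor_a: str, factor_b: str) -> np.ndarray:
    """5x5 table counting ordered level pairs of two factor columns."""
    ia = design.factors.index(factor_a)
    ib = design.factors.index(factor_b)
    counts = np.zeros((N_LEVELS, N_LEVELS), dtype=int)
    for a, b in zip(design.codes[:, ia], design.codes[:, ib]):
        counts[a, b] += 1
    return counts
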