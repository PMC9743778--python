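"""Reading and writing the tab-delimited interchange formats.

Counts: samples as rows, taxa as columns, header row of taxon ids, first
column ``sample_id``.  Covariates: ``sample_id`` plus one column per
covariate.  Truth: long format ``taxon_id, factor, is_da, multiplier``.
Run configuration: YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import CountTable, CountTableError, get_family
from .prr import DesignSpec, encode_interest
from .simulate import SimulationConfig, SimulationTruth

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_covariates",
    "write_covariates",
    "read_truth",
    "write_truth",
    "parse_formula",
    "build_design",
    "RunConfig",
]


def read_count_table(path) -> CountTable:
    """Read a samples x taxa count table from tab-delimited text."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CountTableError(f"duplicate sample id {dup!r} in {path}")
    if pd.Index(df.columns).duplicated().any():
        raise CountTableError(f"duplicate taxon ids in {path}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[
            [not np.issubdtype(d, np.number) for d in df.dtypes]
        ][0]
        raise CountTableError(f"non-numeric count column {bad!r} in {path}")
    return CountTable(
        counts=values,
        sample_ids=[str(i) for i in df.index],
        taxon_ids=[str(c) for c in df.columns],
    )


def write_count_table(table: CountTable, path) -> None:
    df = pd.DataFrame(
        table.counts, index=pd.Index(table.sample_ids, name="sample_id"),
        columns=table.taxon_ids,
    )
    df.to_csv(path, sep="\t")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"covariate table {path} lacks a sample_id column")
    return df


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index=False)


def write_truth(truth: SimulationTruth, path) -> None:
    rows = []
    for factor in truth.da_mask.index:
        mult = truth.multipliers.get(factor, float("nan"))
        for taxon, is_da in truth.da_mask.loc[factor].items():
            rows.append(
                {"taxon_id": taxon, "factor": factor,
                 "is_da": int(is_da), "multiplier": mult}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"taxon_id", "factor", "is_da"}
    if not needed <= set(df.columns):
        raise ValueError(f"truth table {path} lacks columns {needed}")
    return df


def parse_formula(formula: str) -> tuple[list[str], Optional[list[str]]]:
    """Parse a minimal two-part formula string.

    ``"count ~ diet + age | zero ~ diet"`` yields
    ``(['diet', 'age'], ['diet'])``; the zero part is optional and the
    left-hand labels are ignored.  ``"~ 1"`` (or an empty right-hand side)
    means intercept-only.  The covariate of interest is configured
    separately, never inside the formula.
    """
    parts = formula.split("|")
    if len(parts) > 2:
        raise ValueError(f"at most one '|' allowed in formula {formula!r}")

    def rhs(part: str) -> list[str]:
        expr = part.split("~")[-1]
        terms = [t.strip() for t in expr.split("+")]
        return [t for t in terms if t not in ("", "1")]

    count_rhs = rhs(parts[0])
    zero_rhs = rhs(parts[1]) if len(parts) == 2 else None
    return count_rhs, zero_rhs


def build_design(
    covariates: pd.DataFrame,
    interest: str,
    count_nuisance: Sequence[str] = (),
    zero_nuisance: Optional[Sequence[str]] = None,
    interest_in_zero: bool = True,
    reference=None,
) -> DesignSpec:
    """Assemble the interest/nuisance design blocks from a covariate table.

    The nuisance blocks always carry an intercept; categorical covariates
    are treatment coded.  ``zero_nuisance=None`` reuses the count-component
    nuisance terms (the common X = Z case); pass ``interest_in_zero=False``
    to test the covariate of interest in the count component only.
    """
    if interest not in covariates.columns:
        raise ValueError(f"interest covariate {interest!r} not in covariate table")
    n = len(covariates)

    def block(terms: Sequence[str]) -> np.ndarray:
        cols = [np.ones((n, 1))]
        for term in terms:
            if term not in covariates.columns:
                raise ValueError(f"covariate {term!r} not in covariate table")
            mat, _ = encode_interest(covariates[term], name=term)
            cols.append(mat)
        return np.hstack(cols)

    X_int, names = encode_interest(
        covariates[interest], reference=reference, name=interest
    )
    X_nui = block([t for t in count_nuisance if t != interest])
    zero_terms = count_nuisance if zero_nuisance is None else zero_nuisance
    Z_nui = block([t for t in zero_terms if t != interest])
    return DesignSpec(
        X_interest=X_int,
        X_nuisance=X_nui,
        Z_interest=X_int.copy() if interest_in_zero else None,
        Z_nuisance=Z_nui,
        interest_names=names,
    )


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    When ``counts_path`` is unset the data are simulated from ``simulation``;
    otherwise counts/covariates (and optionally truth) are loaded from the
    given tab-delimited files.
    """

    families: list[str] = field(
        default_factory=lambda: ["Poisson", "ZINegativeBinomial"]
    )
    test_types: list[str] = field(default_factory=lambda: ["loglik", "llperm"])
    formula: str = "count ~ diet | zero ~ diet"
    interest: str = "diet"
    B: int = 1000
    gamma: float = 0.05
    repetitions: int = 5
    seed: int = 0
    n_jobs: int = 1
    counts_path: Optional[str] = None
    covariates_path: Optional[str] = None
    truth_path: Optional[str] = None
    output_dir: Optional[str] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for fam in self.families:
            get_family(fam)  # raises on an invalid family name
        bad = set(self.test_types) - {"loglik", "llperm"}
        if bad:
            raise ValueError(f"unknown test types: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(**raw, simulation=sim)
        return cfg

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        raw = plain(dataclasses.asdict(self))
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
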