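"""Group-mean expression profiling, fold-change selection and 2^-ddCq.

Differential expression here is the simple ratio rule used for network
gene selection: per-gene arithmetic means on the linear scale in the
case and reference groups, log2 of their ratio, and a symmetric log2
cutoff (default +-1) classifying genes as up / down / unchanged.
Relative qPCR quantification follows the standard ddCq scheme: target
Cq is normalised to a housekeeping gene within each group (dCq), the
reference group's dCq is subtracted (ddCq), and fold change is
2 ** -ddCq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

DirectionStatus = str  # "higher" | "lower" | "equal"
ConsensusStatus = str  # "up" | "down" | "discordant" | "insufficient"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample linear-scale expression values with group labels.

    ``values``: DataFrame indexed by unique gene symbols, columns are
    sample identifiers, entries finite and non-negative.  ``group_of``
    maps every sample to a group label (e.g. TNBC / normal).
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParameterError("gene symbols must be unique")
        missing = [s for s in self.values.columns if s not in self.group_of]
        if missing:
            raise ParameterError(f"samples without a group label: {missing[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ParameterError("expression values must be finite and >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    @classmethod
    def read_tsv(cls, expression_path, groups_path) -> "ExpressionMatrix":
        """Read a genes-in-rows TSV and a two-column sample->group TSV."""
        df = pd.read_csv(expression_path, sep="\t", index_col=0)
        grp = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"])
        return cls(df, dict(zip(grp["sample"].astype(str), grp["group"].astype(str))))

    def write_tsv(self, expression_path, groups_path) -> None:
        self.values.to_csv(expression_path, sep="\t")
        with open(groups_path, "w") as fh:
            for s in self.values.columns:
                fh.write(f"{s}\t{self.group_of[s]}\n")


def mean_profiles(m: ExpressionMatrix, groups: Sequence[str]) -> pd.DataFrame:
    """Arithmetic mean of linear values per gene for each group.

    Returns a gene x group DataFrame.  Raises ParameterError for a group
    with no labelled samples.
    """
    cols = {}
    for grp in groups:
        samples = m.samples_in(grp)
        if not samples:
            raise ParameterError(f"group {grp!r} has no samples")
        cols[grp] = m.values[samples].mean(axis=1)
    return pd.DataFrame(cols)


def direction_table(
    profiles: pd.DataFrame,
    case_group: str,
    ref_group: str,
    rel_tol: float = 1e-9,
) -> pd.Series:
    """Per-gene direction call: higher / lower / equal mean in the case group.

    Means are compared with relative tolerance ``rel_tol``; differences
    within tolerance are called ``equal``.
    """
    for grp in (case_group, ref_group):
        if grp not in profiles.columns:
            raise ParameterError(f"group {grp!r} not present in profiles")
    case = profiles[case_group].to_numpy(dtype=float)
    ref = profiles[ref_group].to_numpy(dtype=float)
    scale = np.maximum(np.abs(case), np.abs(ref))
    equal = np.abs(case - ref) <= rel_tol * np.maximum(scale, 1e-300)
    out = np.where(equal, "equal", np.where(case > ref, "higher", "lower"))
    return pd.Series(out, index=profiles.index, name="direction")


@dataclass
class FoldChangeTable:
    """Per-gene fold-change classification.

    ``table`` has columns mean_case, mean_ref, log2fc, status; ``up``
    and ``down`` list the selected genes sorted by |log2fc| descending,
    ties broken by symbol.
    """

    table: pd.DataFrame
    up: list[str]
    down: list[str]
    log2_threshold: float
    pseudocount: float


def select_de_genes(
    m: ExpressionMatrix,
    case_group: str,
    ref_group: str,
    log2_threshold: float = 1.0,
    pseudocount: float = 0.0,
) -> FoldChangeTable:
    """Fold-change gene selection between two groups.

    log2fc = log2((mean_case + pseudocount) / (mean_ref + pseudocount));
    status is ``up`` iff log2fc >= threshold, ``down`` iff <= -threshold,
    ``undefined`` when a group mean is zero with pseudocount disabled,
    otherwise ``unchanged``.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    profiles = mean_profiles(m, [case_group, ref_group])
    mean_case = profiles[case_group].to_numpy(dtype=float)
    mean_ref = profiles[ref_group].to_numpy(dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((mean_case + pseudocount) / (mean_ref + pseudocount))

    undefined = (pseudocount == 0) & ((mean_case == 0) | (mean_ref == 0))
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} gene(s) with a zero group mean and no "
            "pseudocount: status set to 'undefined'",
            stacklevel=2,
        )
    status = np.full(len(log2fc), "unchanged", dtype=object)
    status[log2fc >= log2_threshold] = "up"
    status[log2fc <= -log2_threshold] = "down"
    status[undefined] = "undefined"

    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_ref": mean_ref,
            "log2fc": log2fc,
            "status": status,
        },
        index=profiles.index,
    )

    def selected(which: str) -> list[str]:
        sub = table[table["status"] == which]
        return list(
            sub.reindex(
                sorted(sub.index, key=lambda g: (-abs(sub.loc[g, "log2fc"]), g))
            ).index
        )

    return FoldChangeTable(
        table=table,
        up=selected("up"),
        down=selected("down"),
        log2_threshold=log2_threshold,
        pseudocount=pseudocount,
    )


_UP_WORDS = {"up", "higher"}
_DOWN_WORDS = {"down", "lower"}


def consensus_direction(
    tables: Sequence[Mapping[str, str] | pd.Series],
    min_agreement: int,
) -> dict[str, ConsensusStatus]:
    """Cross-dataset consensus direction call.

    A gene is consensus ``up`` (``down``) iff at least ``min_agreement``
    tables call it up (down) and no table calls the opposite direction;
    genes with opposing calls are ``discordant``; everything else is
    ``insufficient``.  Calls of ``equal``/``unchanged`` count as neither
    direction.  The result is invariant to table order.
    """
    if not tables:
        raise ParameterError("at least one direction table is required")
    if min_agreement > len(tables):
        raise ParameterError("min_agreement cannot exceed the number of tables")

    votes: dict[str, list[int]] = {}
    for t in tables:
        items = t.items() if hasattr(t, "items") else t.iteritems()
        for gene, call in items:
            up, down = votes.setdefault(gene, [0, 0])
            if call in _UP_WORDS:
                votes[gene][0] = up + 1
            elif call in _DOWN_WORDS:
                votes[gene][1] = down + 1

    out: dict[str, ConsensusStatus] = {}
    for gene, (up, down) in votes.items():
        if up > 0 and down > 0:
            out[gene] = "discordant"
        elif up >= min_agreement:
            out[gene] = "up"
        elif down >= min_agreement:
            out[gene] = "down"
        else:
            out[gene] = "insufficient"
    return out


@dataclass
class CqTable:
    """Long-format qPCR quantification cycles.

    ``data`` columns: sample, group, gene, replicate, cq.  The
    housekeeping gene must be measured in every sample.
    """

    data: pd.DataFrame
    housekeeping: str

    REQUIRED = ("sample", "group", "gene", "replicate", "cq")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ParameterError(f"CqTable missing columns: {missing}")
        cq = self.data["cq"].to_numpy(dtype=float)
        if not np.isfinite(cq).all() or (cq <= 0).any():
            raise ParameterError("Cq values must be finite and > 0")

    @classmethod
    def read_tsv(cls, path, housekeeping: str) -> "CqTable":
        return cls(pd.read_csv(path, sep="\t"), housekeeping)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def ddcq_fold_change(
    cq: CqTable,
    case_group: str,
    ref_group: str,
    log2_threshold: float = 1.0,
) -> pd.DataFrame:
    """Relative quantification of every target gene by 2^-ddCq.

    Replicate Cq values are averaged per (sample, gene), then per group.
    dCq(group) = mean Cq(target) - mean Cq(housekeeping); ddCq =
    dCq(case) - dCq(ref); fold_change = 2 ** -ddCq.  A gene is flagged
    significant iff |log2(fold_change)| >= ``log2_threshold``.

    Returns a DataFrame indexed by target gene with columns
    delta_cq_case, delta_cq_ref, ddcq, fold_change, significant.

    Raises
    ------
    DataError
        A sample lacks housekeeping measurements (the message names it).
    """
    df = cq.data
    hk = cq.housekeeping
    for grp in (case_group, ref_group):
        if not (df["group"] == grp).any():
            raise ParameterError(f"group {grp!r} has no rows")
    for sample, sub in df.groupby("sample"):
        if not (sub["gene"] == hk).any():
            raise DataError(f"sample {sample!r} has no housekeeping ({hk}) measurement")

    # replicate mean per (sample, gene), then group mean per gene
    per_sample = df.groupby(["group", "gene", "sample"])["cq"].mean()
    per_group = per_sample.groupby(level=["group", "gene"]).mean()

    rows = {}
    targets = sorted(set(df["gene"]) - {hk})
    for grp in (case_group, ref_group):
        hk_mean = per_group[(grp, hk)]
        rows[grp] = {g: per_group.get((grp, g), np.nan) - hk_mean for g in targets}

    out = pd.DataFrame(
        {
            "delta_cq_case": [rows[case_group][g] for g in targets],
            "delta_cq_ref": [rows[ref_group][g] for g in targets],
        },
        index=pd.Index(targets, name="gene"),
    )
    out["ddcq"] = out["delta_cq_case"] - out["delta_cq_ref"]
    out["fold_change"] = 2.0 ** (-out["ddcq"])
    out["significant"] = np.abs(np.log2(out["fold_change"])) >= log2_threshold
    return out
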