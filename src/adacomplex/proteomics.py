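"""dNSAF quantification of MudPIT spectral counts.

The distributed normalized spectral abundance factor (dNSAF) turns raw
spectral counts into per-run relative abundances.  Spectra from peptides
shared between proteins are first distributed among the sharing proteins
in proportion to their unique spectral counts:

    dSpC_i = uSpC_i + sum_g  sSpC_g * uSpC_i / sum_{k in g} uSpC_k

(groups whose members all lack unique spectra are split equally).  The
distributed counts are then length-normalised and scaled to sum to one
per run:

    dNSAF_i = (dSpC_i / L_i) / sum_m (dSpC_m / L_m)

Proteins are called enriched in a complex when their mean dNSAF across
the chosen runs exceeds a threshold (default 0.035), excluding proteins
at least as abundant in a mock purification.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_DNSAF_THRESHOLD = 0.035


@dataclasses.dataclass
class ProteinRun:
    """Spectral counts for one protein in one MudPIT run.

    ``shared_groups`` lists (group_id, group sSpC) pairs for every shared
    peptide group the protein belongs to; the group's total shared count
    is repeated on every member row.
    """

    protein_id: str
    run_id: str
    length: int
    unique_spectra: int
    shared_groups: list[tuple[str, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.protein_id}: length must be positive")
        if self.unique_spectra < 0:
            raise ValueError(f"{self.protein_id}: negative unique spectra")
        for gid, c in self.shared_groups:
            if c < 0:
                raise ValueError(f"group {gid}: negative shared count")


@dataclasses.dataclass
class DnsafTable:
    """dNSAF values keyed by (protein_id, run_id); sums to 1 per run."""

    entries: dict[tuple[str, str], float]

    @property
    def runs(self) -> list[str]:
        return sorted({r for _, r in self.entries})

    @property
    def proteins(self) -> list[str]:
        return sorted({p for p, _ in self.entries})

    def get(self, protein_id: str, run_id: str) -> float:
        return self.entries.get((protein_id, run_id), 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Protein x run matrix, absent entries as 0."""
        df = pd.DataFrame(0.0, index=self.proteins, columns=self.runs)
        for (p, r), v in self.entries.items():
            df.loc[p, r] = v
        return df


def distribute_shared_spectra(run: Sequence[ProteinRun]) -> dict[str, float]:
    """Distribute shared spectral counts among group members.

    Each group's sSpC is split in proportion to the members' unique
    counts; when no member has unique spectra the split is equal.  The
    total (unique + shared) spectral count is conserved exactly.
    """
    runs = {p.run_id for p in run}
    if len(runs) > 1:
        raise ValueError(f"rows span multiple runs: {sorted(runs)}")
    unique = {p.protein_id: float(p.unique_spectra) for p in run}
    # collect group membership: group_id -> (sSpC, [member ids])
    groups: dict[str, tuple[int, list[str]]] = {}
    for p in run:
        for gid, sspc in p.shared_groups:
            if gid in groups:
                prev_sspc, members = groups[gid]
                if prev_sspc != sspc:
                    raise ValueError(
                        f"group {gid}: inconsistent shared counts "
                        f"({prev_sspc} vs {sspc})"
                    )
                members.append(p.protein_id)
            else:
                groups[gid] = (sspc, [p.protein_id])
    dspc = dict(unique)
    for gid, (sspc, members) in groups.items():
        if len(members) < 2:
            warnings.warn(
                f"shared group {gid} has a single member; "
                "treating its spectra as unique",
                stacklevel=2,
            )
            dspc[members[0]] += sspc
            continue
        anchor = sum(unique[m] for m in members)
        if anchor > 0:
            for m in members:
                dspc[m] += sspc * unique[m] / anchor
        else:
            for m in members:
                dspc[m] += sspc / len(members)
    return dspc


def dnsaf(run: Sequence[ProteinRun]) -> dict[str, float]:
    """Per-protein dNSAF for one run (length-normalised, sums to 1)."""
    dspc = distribute_shared_spectra(run)
    lengths = {p.protein_id: p.length for p in run}
    saf = {pid: dspc[pid] / lengths[pid] for pid in dspc}
    total = sum(saf.values())
    if total == 0:
        raise ValueError("run has no spectra; dNSAF undefined")
    return {pid: v / total for pid, v in saf.items()}


def build_dnsaf_table(rows: Sequence[ProteinRun]) -> DnsafTable:
    """dNSAF for every run present in a multi-run row list."""
    by_run: dict[str, list[ProteinRun]] = {}
    for r in rows:
        by_run.setdefault(r.run_id, []).append(r)
    entries: dict[tuple[str, str], float] = {}
    for run_id, run_rows in by_run.items():
        for pid, v in dnsaf(run_rows).items():
            entries[(pid, run_id)] = v
    return DnsafTable(entries)


def enriched_proteins(
    table: DnsafTable,
    runs: Sequence[str],
    threshold: float = DEFAULT_DNSAF_THRESHOLD,
    mock_run: str | None = None,
) -> list[str]:
    """Proteins whose mean dNSAF over ``runs`` exceeds the threshold.

    When a mock run is given, proteins whose mock dNSAF is at least their
    sample mean are excluded (mock-enriched background).
    """
    if not runs:
        raise ValueError("need at least one run")
    out = []
    for pid in table.proteins:
        mean = float(np.mean([table.get(pid, r) for r in runs]))
        if mean <= threshold:
            continue
        if mock_run is not None and table.get(pid, mock_run) >= mean:
            continue
        out.append(pid)
    return sorted(out)


def abundance_matrix(
    table: DnsafTable,
    sample_runs: Sequence[str],
    average_runs: Sequence[str],
) -> pd.DataFrame:
    """Protein x run dNSAF matrix with an averaged column, rows sorted.

    The extra ``mean`` column averages ``average_runs``; rows are sorted
    by it in decreasing order, ties broken by protein_id.
    """
    for r in list(sample_runs) + list(average_runs):
        if r not in table.runs:
            raise KeyError(f"run {r!r} not in table")
    full = table.to_frame()
    df = full[list(sample_runs)].copy()
    df["mean"] = full[list(average_runs)].mean(axis=1)
    order = sorted(range(len(df)), key=lambda i: (-df["mean"].iloc[i], df.index[i]))
    return df.iloc[order]


# ---------------------------------------------------------------------------
# I/O


def read_spectral_counts(
    counts_path: str | Path, shared_path: str | Path | None = None
) -> list[ProteinRun]:
    """Read counts TSV (protein_id, run_id, length, uSpC) plus optional
    shared-group TSV (group_id, protein_id, run_id, sSpC)."""
    counts = pd.read_csv(counts_path, sep="\t", dtype={"protein_id": str, "run_id": str})
    required = {"protein_id", "run_id", "length", "uSpC"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    shared_map: dict[tuple[str, str], list[tuple[str, int]]] = {}
    if shared_path is not None:
        shared = pd.read_csv(
            shared_path, sep="\t", dtype={"protein_id": str, "run_id": str, "group_id": str}
        )
        for row in shared.itertuples(index=False):
            shared_map.setdefault((row.protein_id, row.run_id), []).append(
                (row.group_id, int(row.sSpC))
            )
    rows = []
    for r in counts.itertuples(index=False):
        rows.append(
            ProteinRun(
                protein_id=r.protein_id,
                run_id=r.run_id,
                length=int(r.length),
                unique_spectra=int(r.uSpC),
                shared_groups=shared_map.get((r.protein_id, r.run_id), []),
            )
        )
    return rows


def write_dnsaf_table(table: DnsafTable, path: str | Path) -> None:
    table.to_frame().rename_axis("protein_id").to_csv(path, sep="\t")
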