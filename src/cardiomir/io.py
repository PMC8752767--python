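"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; tables as tab-separated text with a header line;
traces as CSV with a ``time_ms`` column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refractory import ForceTrace
from .targetome import BindingSiteMatrix, MatureMiRNA, SeedSite, UTRRecord
from .traces import RatioTrace


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    return [MatureMiRNA(id=r.id, sequence=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def read_utr_fasta(path: str | Path) -> list[UTRRecord]:
    return [UTRRecord(gene_id=r.id, sequence=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_sites(sites: Sequence[SeedSite], path: str | Path) -> None:
    """BED-like gene-relative site table."""
    write_table(
        pd.DataFrame(
            [
                {
                    "gene_id": s.gene_id,
                    "start": s.start,
                    "end": s.end,
                    "family_id": s.family_id,
                    "site_type": s.site_type,
                    "conserved": "" if s.conserved is None else s.conserved,
                }
                for s in sites
            ],
            columns=["gene_id", "start", "end", "family_id", "site_type", "conserved"],
        ),
        path,
    )


def write_matrix(matrix: BindingSiteMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("family_id").to_csv(path, sep="\t")


def read_trace_csv(path: str | Path) -> RatioTrace:
    """CSV with columns time_ms, ch1[, ch2]; two channels become ch1/ch2."""
    df = pd.read_csv(path)
    time = df["time_ms"].to_numpy(dtype=float)
    channels = [c for c in df.columns if c != "time_ms"]
    if len(channels) == 1:
        return RatioTrace(time=time, signal=df[channels[0]].to_numpy(dtype=float))
    from .traces import ratio_trace

    return ratio_trace(
        df[channels[0]].to_numpy(dtype=float),
        df[channels[1]].to_numpy(dtype=float),
        time,
        numerator_label=channels[0],
        denominator_label=channels[1],
    )


def write_trace_csv(trace: RatioTrace, path: str | Path, column: str = "signal") -> None:
    pd.DataFrame({"time_ms": trace.time, column: trace.signal}).to_csv(path, index=False)


def read_force_csv(trace_path: str | Path, stimuli_path: str | Path) -> ForceTrace:
    df = pd.read_csv(trace_path)
    stim = pd.read_csv(stimuli_path)
    return ForceTrace(
        time=df["time_ms"].to_numpy(dtype=float),
        force=df["force_mN"].to_numpy(dtype=float),
        stimuli=stim[["time_ms", "type", "block"]],
    )


def write_force_csv(trace: ForceTrace, trace_path: str | Path, stimuli_path: str | Path) -> None:
    pd.DataFrame({"time_ms": trace.time, "force_mN": trace.force}).to_csv(trace_path, index=False)
    trace.stimuli.to_csv(stimuli_path, index=False)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term membership mapping."""
    df = pd.read_csv(path, sep="\t")
    term_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for term, gene in zip(df[term_col].astype(str), df[gene_col].astype(str)):
        out.setdefault(term, set()).add(gene)
    return out


def write_iv_curve(potentials: np.ndarray, densities: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"mV": potentials, "pA_per_pF": densities}).to_csv(path, sep="\t", index=False)
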