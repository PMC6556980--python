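"""Peptide-spectrum-match filtering and decoy-based FDR.

Acceptance rules: PSMs with E-value <= 0.01 (inclusive) are accepted; when
one spectrum matched several peptides across database partitions or across
the protein and genome search spaces, only the best (lowest) E-value match
per (tissue, spectrum) survives; peptides supported by a single spectrum are
rejected unless at least two distinct engines identified them.  Decoy PSMs
travel through the identical path before being counted, and
FDR% = 100 * accepted decoy peptides / accepted target peptides.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .models import PSM, PeptideHit, ValidationError

log = logging.getLogger(__name__)

PSM_COLUMNS = ["spectrum_id", "peptide", "evalue", "engine", "search_space",
               "partition", "is_decoy", "tissue"]

DEFAULT_EVALUE_MAX = 0.01

_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}


def read_psm_table(path: str) -> list[PSM]:
    """Read the tab-separated PSM table.

    The header must contain the named columns (extra columns are ignored).
    Malformed rows (non-positive or unparsable E-value, empty or
    stop-containing peptide, bad decoy flag) are rejected and reported with
    their 1-based file line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"PSM table {path}: missing column(s) {missing}")
    psms: list[PSM] = []
    bad: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        try:
            flag = str(row.is_decoy).strip().lower()
            if flag in _TRUE:
                is_decoy = True
            elif flag in _FALSE:
                is_decoy = False
            else:
                raise ValidationError(f"bad is_decoy value {row.is_decoy!r}")
            psms.append(PSM(spectrum_id=row.spectrum_id, peptide=row.peptide,
                            evalue=float(row.evalue), engine=row.engine,
                            search_space=row.search_space,
                            partition=row.partition, is_decoy=is_decoy,
                            tissue=row.tissue))
        except (ValueError, ValidationError) as exc:
            bad.append((line_no, str(exc)))
    for line_no, msg in bad:
        log.warning("%s line %d rejected: %s", path, line_no, msg)
    return psms


def write_psm_table(psms: Iterable[PSM], path: str) -> None:
    rows = [{c: getattr(p, c if c != "is_decoy" else "is_decoy") for c in PSM_COLUMNS}
            for p in psms]
    df = pd.DataFrame(rows, columns=PSM_COLUMNS)
    df["is_decoy"] = df["is_decoy"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def accept_psms(psms: Sequence[PSM],
                evalue_max: float = DEFAULT_EVALUE_MAX) -> list[PSM]:
    """E-value threshold (inclusive) plus best-match-per-spectrum selection.

    Within each (decoy status, tissue, spectrum) group — pooling all
    database partitions and both search spaces — only the PSM with the
    lowest E-value survives; ties break to the lexicographically smallest
    peptide, then partition.  Idempotent and order-independent.
    """
    best: dict[tuple, PSM] = {}
    for p in psms:
        if p.evalue > evalue_max:
            continue
        key = (p.is_decoy, p.tissue, p.spectrum_id)
        cur = best.get(key)
        if cur is None or (p.evalue, p.peptide, p.partition) < (
                cur.evalue, cur.peptide, cur.partition):
            best[key] = p
    return [best[k] for k in sorted(best)]


def aggregate_hits(psms: Sequence[PSM]) -> list[PeptideHit]:
    """Collapse accepted PSMs into peptide-level hits per tissue."""
    groups: dict[tuple, list[PSM]] = defaultdict(list)
    for p in psms:
        groups[(p.is_decoy, p.tissue, p.peptide)].append(p)
    hits = []
    for (is_decoy, tissue, peptide), members in sorted(groups.items()):
        hits.append(PeptideHit(
            peptide=peptide, tissue=tissue,
            spectra={m.spectrum_id for m in members},
            engines={m.engine for m in members},
            best_evalue=min(m.evalue for m in members),
            is_decoy=is_decoy))
    return hits


def spectral_count_filter(hits: Sequence[PeptideHit]) -> list[PeptideHit]:
    """Reject single-spectrum identifications unless seen by >= 2 engines."""
    return [h for h in hits if len(h.spectra) >= 2 or len(h.engines) >= 2]


def compute_fdr(n_target_accepted: int, n_decoy_accepted: int) -> float:
    """Decoy-based FDR as a percentage, rounded to 2 decimals."""
    if n_target_accepted < 1:
        raise ValidationError("FDR undefined: zero accepted target identifications")
    return round(100.0 * n_decoy_accepted / n_target_accepted, 2)


def filter_pipeline(psms: Sequence[PSM],
                    evalue_max: float = DEFAULT_EVALUE_MAX) -> list[PeptideHit]:
    """Full accept -> aggregate -> spectral-count path (targets and decoys)."""
    return spectral_count_filter(aggregate_hits(accept_psms(psms, evalue_max)))


def fdr_report(psms: Sequence[PSM],
               evalue_max: float = DEFAULT_EVALUE_MAX) -> pd.DataFrame:
    """Per-tissue decoy FDR table after the full filtering path.

    Columns: tissue, n_target, n_decoy, fdr_pct.  Tissues with zero accepted
    targets are reported with NaN FDR.
    """
    hits = filter_pipeline(psms, evalue_max)
    tissues = sorted({h.tissue for h in hits})
    rows = []
    for tissue in tissues:
        nt = sum(1 for h in hits if h.tissue == tissue and not h.is_decoy)
        nd = sum(1 for h in hits if h.tissue == tissue and h.is_decoy)
        rows.append({"tissue": tissue, "n_target": nt, "n_decoy": nd,
                     "fdr_pct": compute_fdr(nt, nd) if nt else float("nan")})
    return pd.DataFrame(rows, columns=["tissue", "n_target", "n_decoy", "fdr_pct"])
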