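"""Optional network access: fetch protein sequences by locus tag.

The seven pomegranate CLC loci are public genome-annotation locus tags;
fetching their protein records needs NCBI access.
Everything else in the package runs offline, so failures here raise
:class:`RemoteUnavailable` rather than crashing callers that can fall
back to synthetic data.
"""

from __future__ import annotations

import io
import json
import urllib.parse
import urllib.request

from .family_identification import ProteinRecord

__all__ = ["PGCLC_LOCUS_TAGS", "RemoteUnavailable", "fetch_proteins_by_locus_tag"]

#: Locus tags of the seven pomegranate CLC genes (public annotation).
PGCLC_LOCUS_TAGS = [
    "CDL15_Pgr005627",
    "CDL15_Pgr027626",
    "CDL15_Pgr013895",
    "CDL15_Pgr008552",
    "CDL15_Pgr019810",
    "CDL15_Pgr012201",
    "CDL15_Pgr015371",
]

_EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


class RemoteUnavailable(RuntimeError):
    """Raised when NCBI cannot be reached or returns no usable data."""


def _get(url: str, timeout: float) -> bytes:
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            return resp.read()
    except Exception as exc:
        raise RemoteUnavailable(f"cannot reach {url.split('?')[0]}: {exc}") from exc


def fetch_proteins_by_locus_tag(
    locus_tags: list[str] | None = None, timeout: float = 15.0
) -> dict[str, list[ProteinRecord]]:
    """Fetch all annotated protein isoforms for each locus tag.

    Returns a mapping locus tag -> protein records (possibly several
    isoforms per locus).  Raises :class:`RemoteUnavailable` when the
    network or NCBI is unavailable.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    locus_tags = locus_tags or PGCLC_LOCUS_TAGS
    out: dict[str, list[ProteinRecord]] = {}
    for tag in locus_tags:
        term = urllib.parse.quote(f"{tag}[All Fields]")
        search_url = (
            f"{_EUTILS}/esearch.fcgi?db=protein&term={term}&retmode=json&retmax=50"
        )
        payload = json.loads(_get(search_url, timeout))
        ids = payload.get("esearchresult", {}).get("idlist", [])
        if not ids:
            raise RemoteUnavailable(f"no protein records found for {tag}")
        fetch_url = (
            f"{_EUTILS}/efetch.fcgi?db=protein&id={','.join(ids)}"
            "&rettype=fasta&retmode=text"
        )
        fasta = _get(fetch_url, timeout).decode()
        records = []
        for header, seq in SimpleFastaParser(io.StringIO(fasta)):
            rid = header.split()[0]
            seq = seq.upper().rstrip("*")
            records.append(ProteinRecord(id=rid, sequence=seq, species="Pgr"))
        if not records:
            raise RemoteUnavailable(f"empty FASTA response for {tag}")
        out[tag] = records
    return out
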