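"""Optional live NCBI E-utilities adapter.

Fetches, per (gene, species), the gene record and its protein RefSeq
products, writing the same on-disk layout :class:`~surfscreen.crossmap.
SequenceStore` reads — so downstream code cannot tell live from fixture
data.  Requests are rate-limited (3/s, the unauthenticated E-utilities
limit) and cached on disk.  All tests run against local fixtures; this
module is only exercised when a network is actually available.
"""

from __future__ import annotations

import json
import time
import urllib.parse
import urllib.request
from pathlib import Path
from xml.etree import ElementTree

from .crossmap import SequenceStore

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
_MIN_INTERVAL = 0.34  # seconds between requests


class NcbiAdapter:
    def __init__(self, cache_dir: str | Path = ".ncbi_cache", timeout: float = 30.0):
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.timeout = timeout
        self._last_request = 0.0

    def _get(self, endpoint: str, **params: str) -> bytes:
        key = endpoint + "?" + urllib.parse.urlencode(sorted(params.items()))
        cache_file = self.cache_dir / (str(abs(hash(key))) + ".cache")
        if cache_file.exists():
            return cache_file.read_bytes()
        wait = self._last_request + _MIN_INTERVAL - time.monotonic()
        if wait > 0:
            time.sleep(wait)
        url = f"{EUTILS}/{endpoint}?{urllib.parse.urlencode(params)}"
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            data = resp.read()
        self._last_request = time.monotonic()
        cache_file.write_bytes(data)
        return data

    def search_gene(self, gene: str, species: str) -> list[str]:
        data = self._get(
            "esearch.fcgi",
            db="gene",
            term=f"{gene}[Gene Name] AND {species}[Organism]",
            retmode="json",
        )
        return json.loads(data)["esearchresult"].get("idlist", [])

    def gene_refseqs(self, gene_id: str) -> list[str]:
        data = self._get("efetch.fcgi", db="gene", id=gene_id, retmode="xml")
        root = ElementTree.fromstring(data)
        accs = set()
        for el in root.iter("Gene-commentary_accession"):
            if el.text and el.text.startswith(("NP_", "XP_")):
                accs.add(el.text)
        return sorted(accs)

    def fetch_protein_fasta(self, refseq_id: str) -> tuple[str, str]:
        data = self._get(
            "efetch.fcgi", db="protein", id=refseq_id, rettype="fasta", retmode="text"
        )
        lines = data.decode().strip().splitlines()
        description = lines[0].lstrip(">")
        return description, "".join(lines[1:])

    def populate_store(
        self, genes: list[str], species: list[str], store: SequenceStore
    ) -> SequenceStore:
        """Download every (gene, species) combination into the store."""
        for sp in species:
            for gene in genes:
                for gid in self.search_gene(gene, sp):
                    for refseq in self.gene_refseqs(gid):
                        desc, seq = self.fetch_protein_fasta(refseq)
                        if seq:
                            store.add_product(sp, gene, refseq, desc, seq)
        return store
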