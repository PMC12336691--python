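"""Canonicalization of TRB gene calls across sequencing dialects.

Different pipelines emit the same gene under different spellings:
IMGT-style ``TRBV5-6*01`` (with allele), immunoSEQ-style ``TCRBV05-06``,
or already-canonical ``TRBV05-06``. All repertoire comparisons in this
package are at gene resolution, so gene calls are normalized to a single
canonical spelling before any matching: ``TRB`` prefix, allele suffix
stripped, family and gene numbers zero-padded to two digits.
"""

from __future__ import annotations

import re

__all__ = ["canonical_gene"]

_GENE_RE = re.compile(
    r"^(?:TR|TCR)(?P<chain>[ABGD])(?P<region>[VDJ])"
    r"(?P<family>\d+)(?:[-/](?P<gene>\d+))?"
    r"(?:\*(?P<allele>[\w:]+))?$"
)


def canonical_gene(call: str) -> str:
    """Return the canonical gene-level name for a V/D/J gene call.

    The allele designation (``*01``) is dropped and family/gene numbers
    are zero-padded to width 2, e.g. ``TRBV5-6*01`` -> ``TRBV05-06`` and
    ``TCRBJ02-07`` -> ``TRBJ02-07``. Canonical names are fixed points.
    Calls that do not look like a receptor gene (empty strings,
    ``unresolved``, multi-gene ambiguity strings) are returned stripped
    but otherwise unchanged.
    """
    call = call.strip()
    m = _GENE_RE.match(call.upper())
    if m is None:
        return call
    name = f"TR{m['chain']}{m['region']}{int(m['family']):02d}"
    if m["gene"] is not None:
        name += f"-{int(m['gene']):02d}"
    return name
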