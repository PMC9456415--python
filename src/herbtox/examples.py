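"""Bundled worked-example data: published annotation retrieve sequences for
three sterol-like compounds (hepatotoxicity and carcinogenicity), used as
regression anchors for the calibration statistics."""

from __future__ import annotations

import importlib.resources

from .calibration import RetrieveSequence, read_retrieves


def load_example_retrieves() -> dict[tuple[str, str], RetrieveSequence]:
    """Load the bundled retrieve sequences keyed by (query_id, endpoint)."""
    ref = importlib.resources.files("herbtox") / "data" / "example_retrieves.csv"
    with importlib.resources.as_file(ref) as path:
        seqs = read_retrieves(path)
    return {(s.query_id, s.endpoint): s for s in seqs}
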