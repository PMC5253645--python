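"""Small shared helpers."""

from __future__ import annotations

import pandas as pd


def as_frame(obj) -> pd.DataFrame:
    """Accept either a genes x cells DataFrame or a NormalizedMatrix-like
    wrapper exposing ``.values`` as that DataFrame."""
    if isinstance(obj, pd.DataFrame):
        return obj
    return obj.values
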