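"""Bundled reference datasets for the coastal California gnatcatcher system.

Two small published summary tables accompany the package so that the
dispersal-dyad and diversity-vs-habitat analyses can be exercised on real
numbers without any download:

* ``load_ccg_dyads`` — 34 supported first-order relative dyads with
  pairwise support, Euclidean and least-cost-path distances (m) between
  capture locations, and the sampling aggregation of each member.
* ``load_ccg_diversity`` — per-aggregation genetic diversity indices
  (Ho, He, F, r, Ar) and percent suitable habitat within a 30-km buffer.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .kinship import RelativeDyad


def _read(name: str) -> pd.DataFrame:
    with resources.files("kinscape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_ccg_dyads(as_frame: bool = False):
    """The 34 gnatcatcher first-order relative dyads (list of RelativeDyad)."""
    df = _read("ccg_dyads.csv")
    if as_frame:
        return df
    return [RelativeDyad(str(r.id1), str(r.id2), float(r.prob),
                         euclid_m=float(r.euclid_m), lcp_m=float(r.lcp_m),
                         region1=r.region1, region2=r.region2)
            for r in df.itertuples()]


def load_ccg_diversity() -> pd.DataFrame:
    """Per-aggregation diversity indices and 30-km percent suitable habitat."""
    return _read("ccg_diversity.csv")
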