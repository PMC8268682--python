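"""Packaged transcriptions of the published satellitome tables.

The composition table (52 families, 53 variant rows) and the two chromosome
occupancy panels (one per genome assembly) were transcribed once from print
into TSV and frozen; the loaders verify sha256 checksums so the fixtures
cannot drift silently. Thousands separators were normalized to plain
integers at transcription and "-" Repbase entries to empty strings.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

PANEL_IDS = ("GCA_902806645.1", "GCA_011032805.1")


class FixtureChecksumError(RuntimeError):
    """A packaged table no longer matches its frozen checksum."""


def _data_file(name: str) -> bytes:
    ref = resources.files("satorg.data").joinpath(name)
    return ref.read_bytes()


def _verified(name: str) -> bytes:
    raw = _data_file(name)
    checksums = json.loads(_data_file("checksums.json"))
    digest = hashlib.sha256(raw).hexdigest()
    if checksums.get(name) != digest:
        raise FixtureChecksumError(
            f"{name}: sha256 {digest} != frozen {checksums.get(name)}"
        )
    return raw


def load_table1() -> pd.DataFrame:
    """Composition rows: one per consensus variant.

    Columns: family_id, variant_id, monomer_length, genome_pct,
    satellitome_pct, at_pct, repbase_class (empty string = no annotation).
    """
    from io import BytesIO

    df = pd.read_csv(BytesIO(_verified("table1.tsv")), sep="\t",
                     keep_default_na=False,
                     dtype={"repbase_class": str})
    return df


def load_table2(panel: str) -> pd.DataFrame:
    """Occupancy rows for one assembly panel.

    Same schema as :func:`satorg.summary.occupancy_table` output (presence
    columns are 0/1; GCA_011032805.1 reports no unplaced scaffolds, so its
    panel has no scaffold column). ``df.attrs["chromosome_ids"]`` carries
    the chromosome column order.
    """
    from io import BytesIO

    if panel not in PANEL_IDS:
        raise ValueError(f"unknown panel {panel!r}; expected one of "
                         f"{PANEL_IDS}")
    import re
    df = pd.read_csv(BytesIO(_verified(f"table2_{panel}.tsv")), sep="\t")
    chroms = [c for c in df.columns if re.fullmatch(r"(LG|chr)\d+", c)]
    df[chroms] = df[chroms].astype(bool)
    df.attrs["chromosome_ids"] = chroms
    return df
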