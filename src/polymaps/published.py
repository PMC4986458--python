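"""Loaders for the published octoploid strawberry reference tallies.

These small tables transcribe the region-classification counts and the
introgression-cluster list reported for the F. virginiana and F. chiloensis
targeted-capture linkage maps.  They serve as fixed reference inputs for
summary reproduction (table arithmetic, cluster geometry) -- the pipeline
itself never reads them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .introgression import IntrogressionCluster


def _read(name: str) -> pd.DataFrame:
    with resources.files("polymaps").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_region_class_counts() -> pd.DataFrame:
    """Per-(signal, subgenome) 1-kb region counts by chromosome."""
    return _read("region_class_counts.tsv")


def load_cluster_table() -> pd.DataFrame:
    """The 48 published introgression clusters with reference intervals."""
    return _read("introgression_clusters.tsv")


def published_clusters() -> list[IntrogressionCluster]:
    df = load_cluster_table()
    return [
        IntrogressionCluster(
            subgenome=row.subgenome,
            chromosome=str(row.chromosome),
            first_site=int(row.start),
            last_site=int(row.end),
            region_count=int(row.regions),
            maps=frozenset(str(row.maps).split(",")),
        )
        for row in df.itertuples()
    ]
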