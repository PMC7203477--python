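"""HDF5 serialization for evaluation pair sets and dictionaries.

Both objects carry provenance ((subject_id, trial_id) source sets per
signal), stored as JSON strings so audits survive a round trip.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .dictionary import Dictionary
from .pairing import TestPairSet


def _sources_to_json(sources: list) -> np.ndarray:
    return np.array(
        [json.dumps(sorted([list(s) for s in src])) for src in sources], dtype=object
    )


def _sources_from_json(raw) -> list:
    out = []
    for item in raw:
        if isinstance(item, bytes):
            item = item.decode()
        out.append(frozenset(tuple(x) for x in json.loads(item)))
    return out


def save_pair_set(pairs: TestPairSet, path) -> None:
    str_t = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["scheme"] = pairs.scheme
        f.create_dataset("queries", data=pairs.queries)
        f.create_dataset("knowns", data=pairs.knowns)
        f.create_dataset("query_classes", data=np.array([str(c) for c in pairs.query_classes], dtype=object), dtype=str_t)
        f.create_dataset("known_classes", data=np.array([str(c) for c in pairs.known_classes], dtype=object), dtype=str_t)
        f.create_dataset("query_sources", data=_sources_to_json(pairs.query_sources), dtype=str_t)
        f.create_dataset("known_sources", data=_sources_to_json(pairs.known_sources), dtype=str_t)


def load_pair_set(path) -> TestPairSet:
    with h5py.File(path, "r") as f:
        def strs(key):
            return np.array([v.decode() if isinstance(v, bytes) else v for v in f[key][()]],
                            dtype=object)

        return TestPairSet(
            queries=f["queries"][()],
            query_classes=strs("query_classes"),
            query_sources=_sources_from_json(f["query_sources"][()]),
            knowns=f["knowns"][()],
            known_classes=strs("known_classes"),
            known_sources=_sources_from_json(f["known_sources"][()]),
            scheme=f.attrs["scheme"],
        )


def save_dictionary(d: Dictionary, path) -> None:
    str_t = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["entry_kind"] = d.entry_kind
        f.attrs["k"] = d.k
        f.attrs["source_pool_id"] = d.source_pool_id
        f.attrs["label_set"] = json.dumps(list(d.label_set))
        f.create_dataset("signals", data=d.signals)
        f.create_dataset("classes", data=np.array([str(c) for c in d.classes], dtype=object), dtype=str_t)
        f.create_dataset("sources", data=_sources_to_json(d.sources), dtype=str_t)


def load_dictionary(path) -> Dictionary:
    with h5py.File(path, "r") as f:
        classes = np.array(
            [v.decode() if isinstance(v, bytes) else v for v in f["classes"][()]],
            dtype=object,
        )
        return Dictionary(
            signals=f["signals"][()],
            classes=classes,
            sources=_sources_from_json(f["sources"][()]),
            label_set=tuple(json.loads(f.attrs["label_set"])),
            entry_kind=f.attrs["entry_kind"],
            k=int(f.attrs["k"]),
            source_pool_id=f.attrs["source_pool_id"],
        )
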