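"""Dataset serialization.

Synthetic datasets live in one HDF5 container per run:

* ``/cells/ssc``   — (N, D, H, W) float32 3D SSC volumes
* ``/cells/trans`` — (N, H, W) float32 transmission images
* ``/cells/meta``  — table of cell_id, fl_0h, fl_48h, true_class,
  dispense_index (compound dtype), plus a ``scenario`` attribute

Dispense sequences use the CSV dialect from :mod:`cytofuse.sequences`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .errors import InputError
from .synthetic_data import CellRecord

_META_DTYPE = np.dtype([
    ("cell_id", "<i8"),
    ("fl_0h", "<f8"),
    ("fl_48h", "<f8"),
    ("true_class", "<i8"),
    ("dispense_index", "<i8"),
])


def write_dataset(records: list[CellRecord], path: str | Path) -> None:
    if not records:
        raise InputError("cannot write an empty dataset")
    ssc = np.stack([r.ssc_image for r in records]).astype(np.float32)
    trans = np.stack([r.trans_image for r in records]).astype(np.float32)
    meta = np.array(
        [(r.cell_id, r.fl_0h, r.fl_48h, r.true_class, r.dispense_index)
         for r in records],
        dtype=_META_DTYPE,
    )
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("cells")
        grp.create_dataset("ssc", data=ssc)
        grp.create_dataset("trans", data=trans)
        grp.create_dataset("meta", data=meta)
        grp.attrs["scenario"] = records[0].scenario_label


def read_dataset(path: str | Path) -> list[CellRecord]:
    with h5py.File(path, "r") as fh:
        grp = fh["cells"]
        ssc = grp["ssc"][...]
        trans = grp["trans"][...]
        meta = grp["meta"][...]
        scenario = grp.attrs["scenario"]
    return [
        CellRecord(
            cell_id=int(m["cell_id"]),
            ssc_image=ssc[i],
            trans_image=trans[i],
            fl_0h=float(m["fl_0h"]),
            fl_48h=float(m["fl_48h"]),
            true_class=int(m["true_class"]),
            scenario_label=str(scenario),
            dispense_index=int(m["dispense_index"]),
        )
        for i, m in enumerate(meta)
    ]
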