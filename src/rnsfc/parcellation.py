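"""Abstract cortical parcellation: fine ROIs grouped into coarse modules.

A parcellation maps each fine region of interest (ROI) to exactly one
module, and each module to one lobe and one hemisphere.  The default
layout mirrors a 218-ROI cortical atlas reduced to 44 modules (22 per
hemisphere, spread over frontal/temporal/parietal/occipital lobes), which
yields 44*45/2 = 990 unordered module-module connections including the
within-module entries.

The geometry is abstract: ROI and module identities are labels, not
coordinates.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

PARCELLATION_COLUMNS = ("roi_id", "roi_label", "module_id", "lobe", "hemisphere")
DEFAULT_LOBES = ("frontal", "temporal", "parietal", "occipital")


class Parcellation:
    """ROI -> module -> (lobe, hemisphere) lookup table.

    Parameters
    ----------
    frame
        Table with columns ``roi_id, roi_label, module_id, lobe,
        hemisphere``; one row per ROI.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in PARCELLATION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"parcellation table missing columns {missing}")
        frame = frame.loc[:, list(PARCELLATION_COLUMNS)].reset_index(drop=True)
        dup = frame["roi_id"][frame["roi_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate roi_id entries: {sorted(set(dup))}")
        bad_hemi = set(frame["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere labels must be L or R, got {sorted(bad_hemi)}")
        for col in ("lobe", "hemisphere"):
            per_module = frame.groupby("module_id")[col].nunique()
            mixed = per_module[per_module > 1]
            if len(mixed):
                raise ValueError(
                    f"modules with inconsistent {col}: {sorted(mixed.index)}"
                )
        self.frame = frame
        self._module_of = dict(zip(frame["roi_id"], frame["module_id"]))
        mods = frame.drop_duplicates("module_id")
        self._lobe_of = dict(zip(mods["module_id"], mods["lobe"]))
        self._hemisphere_of = dict(zip(mods["module_id"], mods["hemisphere"]))
        self.module_ids: list[int] = sorted(self._lobe_of)

    # -- basic lookups -------------------------------------------------
    @property
    def roi_ids(self) -> list[str]:
        return list(self.frame["roi_id"])

    @property
    def n_rois(self) -> int:
        return len(self.frame)

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    @property
    def n_connections(self) -> int:
        """Unordered module pairs including within-module entries."""
        m = self.n_modules
        return m * (m + 1) // 2

    @property
    def lobes(self) -> list[str]:
        return sorted(set(self._lobe_of.values()))

    def module_of(self, roi_id: str) -> int:
        try:
            return self._module_of[roi_id]
        except KeyError:
            raise KeyError(f"ROI {roi_id!r} is not in the parcellation") from None

    def lobe_of(self, module_id: int) -> str:
        return self._lobe_of[module_id]

    def hemisphere_of(self, module_id: int) -> str:
        return self._hemisphere_of[module_id]

    def modules_in(self, lobe: str | None = None, hemisphere: str | None = None) -> list[int]:
        out = []
        for m in self.module_ids:
            if lobe is not None and self._lobe_of[m] != lobe:
                continue
            if hemisphere is not None and self._hemisphere_of[m] != hemisphere:
                continue
            out.append(m)
        return out

    def module_rows(self, roi_order: list[str]) -> dict[int, np.ndarray]:
        """Row positions of each module's ROIs within ``roi_order``."""
        rows: dict[int, list[int]] = {m: [] for m in self.module_ids}
        for pos, roi in enumerate(roi_order):
            rows[self.module_of(roi)].append(pos)
        return {m: np.asarray(v, dtype=int) for m, v in rows.items()}

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"parcellation file not found: {path}")
        frame = pd.read_csv(path, sep="\t", dtype={"roi_id": str, "roi_label": str})
        return cls(frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Parcellation) and self.frame.equals(other.frame)


def make_parcellation(
    n_rois: int = 218,
    n_modules: int = 44,
    lobe_names: tuple[str, ...] = DEFAULT_LOBES,
) -> Parcellation:
    """Build a synthetic labeled parcellation.

    Modules are split as evenly as possible between hemispheres (left
    first), assigned round-robin to lobes within each hemisphere, and ROIs
    are distributed near-evenly across modules.
    """
    if n_modules < 1 or n_rois < n_modules:
        raise ValueError("need n_rois >= n_modules >= 1")
    n_left = (n_modules + 1) // 2
    rows = []
    roi_chunks = np.array_split(np.arange(n_rois), n_modules)
    for m in range(n_modules):
        hemi = "L" if m < n_left else "R"
        within = m if hemi == "L" else m - n_left
        lobe = lobe_names[within % len(lobe_names)]
        for k, r in enumerate(roi_chunks[m]):
            rows.append(
                {
                    "roi_id": f"roi{r:03d}",
                    "roi_label": f"{lobe}_{hemi}_m{m:02d}_{k}",
                    "module_id": m,
                    "lobe": lobe,
                    "hemisphere": hemi,
                }
            )
    return Parcellation(pd.DataFrame(rows))


@lru_cache(maxsize=1)
def default_parcellation() -> Parcellation:
    """The default 218-ROI / 44-module parcellation."""
    return make_parcellation()
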