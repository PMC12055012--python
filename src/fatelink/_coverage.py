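"""Internal vectorized fragment/window overlap machinery.

Fragments are indexed per chromosome by sorted start position; a window
query slices candidates by ``start in [ws - max_len, we)`` and filters on
``end > ws``. All tallies are count-weighted (a record with count k stands
for k identical fragments).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class FragmentIndex:
    def __init__(self, fragments: pd.DataFrame, barcodes: list[str]):
        self.barcodes = list(barcodes)
        self._code = {b: i for i, b in enumerate(self.barcodes)}
        self.n_barcodes = len(self.barcodes)
        self._by_chrom: dict[str, tuple] = {}
        if fragments is None or len(fragments) == 0:
            return
        bc_codes = fragments["barcode"].map(self._code)
        keep = bc_codes.notna().to_numpy()
        frag = fragments.loc[keep]
        codes = bc_codes.to_numpy()[keep].astype(np.int64)
        for chrom, idx in frag.groupby("chrom").indices.items():
            sub_start = frag["start"].to_numpy()[idx]
            order = np.argsort(sub_start, kind="stable")
            self._by_chrom[str(chrom)] = (
                sub_start[order],
                frag["end"].to_numpy()[idx][order],
                codes[idx][order],
                frag["count"].to_numpy()[idx][order],
                int((frag["end"].to_numpy()[idx] - sub_start).max()),
            )

    def _candidates(self, chrom: str, ws: int, we: int):
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        fs, fe, fbc, fcnt, max_len = entry
        lo = np.searchsorted(fs, ws - max_len, side="left")
        hi = np.searchsorted(fs, we, side="left")
        sel = slice(lo, hi)
        mask = fe[sel] > ws
        return fs[sel][mask], fe[sel][mask], fbc[sel][mask], fcnt[sel][mask]

    def window_counts(self, chrom: str, ws: int, we: int) -> np.ndarray:
        """Per-barcode count-weighted number of fragments overlapping [ws, we)."""
        cand = self._candidates(chrom, ws, we)
        out = np.zeros(self.n_barcodes)
        if cand is None or len(cand[0]) == 0:
            return out
        fs, fe, fbc, fcnt = cand
        np.add.at(out, fbc, fcnt)
        return out

    def window_overlap_bp(self, chrom: str, ws: int, we: int) -> np.ndarray:
        """Per-barcode count-weighted overlap base pairs with [ws, we)."""
        cand = self._candidates(chrom, ws, we)
        out = np.zeros(self.n_barcodes)
        if cand is None or len(cand[0]) == 0:
            return out
        fs, fe, fbc, fcnt = cand
        ov = np.minimum(fe, we) - np.maximum(fs, ws)
        np.add.at(out, fbc, fcnt * ov)
        return out

    def length_tallies(self, mono=(147, 294), short_max=147) -> tuple[np.ndarray, np.ndarray]:
        """Count-weighted (mono-nucleosome, short) fragment tallies per barcode."""
        mono_out = np.zeros(self.n_barcodes)
        short_out = np.zeros(self.n_barcodes)
        for fs, fe, fbc, fcnt, _ in self._by_chrom.values():
            ln = fe - fs
            m = (ln >= mono[0]) & (ln <= mono[1])
            s = ln < short_max
            np.add.at(mono_out, fbc[m], fcnt[m])
            np.add.at(short_out, fbc[s], fcnt[s])
        return mono_out, short_out

    def totals(self) -> np.ndarray:
        out = np.zeros(self.n_barcodes)
        for _, _, fbc, fcnt, _ in self._by_chrom.values():
            np.add.at(out, fbc, fcnt)
        return out
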