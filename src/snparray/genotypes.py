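"""Genotype matrix container shared by the calling, QC, popgen and GWAS layers.

Calls are diploidized states: the two homozygote classes ``AA``/``BB``, the
heterozygote ``AB``, the no-signal state ``NG`` (present locus, absent signal,
typically structural variation or an In-Del under the probe) and the failed /
off-cluster state ``--``.  Internally calls are stored as a compact int8 code
matrix (markers x samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical call states and their internal codes
CALL_CODES = {"AA": 0, "AB": 1, "BB": 2, "NG": -1, "--": -2}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}

#: dosage of the B (alt) allele per called state
_DOSAGE = {0: 0.0, 1: 1.0, 2: 2.0, -1: np.nan, -2: np.nan}


class GenotypeMatrix:
    """Markers x samples matrix of diploidized genotype calls.

    Parameters
    ----------
    calls
        DataFrame indexed by marker id with sample ids as columns.  Values may
        be call strings (``AA``/``AB``/``BB``/``NG``/``--``) or int8 codes.
    """

    def __init__(self, calls: pd.DataFrame):
        if calls.index.has_duplicates or calls.columns.has_duplicates:
            raise ValueError("duplicate marker or sample ids")
        if calls.values.dtype.kind in "OUS":
            bad = set(np.unique(calls.values.astype(str))) - set(CALL_CODES)
            if bad:
                raise ValueError(f"unknown call states: {sorted(bad)}")
            codes = calls.apply(lambda col: col.map(CALL_CODES)).astype(np.int8)
        else:
            codes = calls.astype(np.int8)
            bad_codes = set(np.unique(codes.values)) - set(CODE_CALLS)
            if bad_codes:
                raise ValueError(f"unknown call codes: {sorted(bad_codes)}")
        self._codes = codes

    # -- basic access ------------------------------------------------------
    @property
    def codes(self) -> pd.DataFrame:
        """Int8 code matrix (0=AA, 1=AB, 2=BB, -1=NG, -2=missing)."""
        return self._codes

    @property
    def markers(self) -> pd.Index:
        return self._codes.index

    @property
    def samples(self) -> pd.Index:
        return self._codes.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self._codes.shape

    def calls(self) -> pd.DataFrame:
        """Call matrix as strings."""
        return self._codes.apply(lambda col: col.map(CODE_CALLS))

    def dosage(self) -> pd.DataFrame:
        """Alt-allele dosage (0/1/2) with NaN for NG and missing."""
        arr = self._codes.values.astype(float)
        arr[arr < 0] = np.nan
        return pd.DataFrame(arr, index=self.markers, columns=self.samples)

    def subset(self, markers=None, samples=None) -> "GenotypeMatrix":
        codes = self._codes
        if markers is not None:
            codes = codes.loc[markers]
        if samples is not None:
            codes = codes[list(samples)]
        return GenotypeMatrix(codes)

    # -- summary accessors -------------------------------------------------
    def called_mask(self, count_ng: bool = False) -> pd.DataFrame:
        """Boolean mask of definite calls; NG counts only if requested."""
        ok = self._codes.values >= 0
        if count_ng:
            ok = ok | (self._codes.values == CALL_CODES["NG"])
        return pd.DataFrame(ok, index=self.markers, columns=self.samples)

    def call_rate(self, axis: str = "marker", count_ng: bool = False) -> pd.Series:
        """Fraction of definite calls per marker (default) or per sample.

        By default NG and ``--`` both reduce the call rate (both are uncalled
        states); ``count_ng=True`` counts NG as called.
        """
        ok = self.called_mask(count_ng=count_ng)
        if axis == "marker":
            return ok.mean(axis=1)
        if axis == "sample":
            return ok.mean(axis=0)
        raise ValueError("axis must be 'marker' or 'sample'")

    def allele_counts(self) -> pd.DataFrame:
        """Per-marker counts of ref and alt alleles among called genotypes."""
        d = self.dosage().values
        called = ~np.isnan(d)
        n_called = called.sum(axis=1)
        alt = np.nansum(d, axis=1)
        ref = 2.0 * n_called - alt
        return pd.DataFrame({"ref": ref, "alt": alt}, index=self.markers)

    def maf(self) -> pd.Series:
        """Minor-allele frequency per marker; NaN where no genotype was called."""
        ac = self.allele_counts()
        total = ac["ref"] + ac["alt"]
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(total > 0, ac["alt"] / total, np.nan)
        return pd.Series(np.minimum(p_alt, 1.0 - p_alt), index=self.markers)

    def __repr__(self) -> str:  # pragma: no cover
        m, n = self.shape
        return f"GenotypeMatrix({m} markers x {n} samples)"
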