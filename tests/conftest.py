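import numpy as np

from megnets.containers import ParcelTimeSeries


def make_ts(data, fs=250.0, **kw):
    """Wrap a raw array as a ParcelTimeSeries (shared test helper)."""
    return ParcelTimeSeries(data=np.asarray(data, dtype=float), fs=fs, **kw)
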