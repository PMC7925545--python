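"""Reference feature matrix for lion-modified long bones.

Eight element-side rows (left/right humerus, femur, radius-ulna, tibia) by
six point-process summary features: the mean observed K, F, G and
pair-correlation curves, the mean nearest-neighbour distance (mm) and the
global intensity.  The matrix summarises the tooth-mark point patterns of a
wild-lion-consumed medium-ungulate carcass assemblage and serves as the
package's worked example for multi-element clustering: the four elements are
recovered as four clusters, each containing its own left and right sides.

The intensity column is in scaled (dimensionless) print units; its absolute
scale is not comparable across datasets and the worked example standardises
all columns before clustering, so the scale drops out.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["LION_FEATURE_TABLE", "lion_feature_table"]

_ROWS = {
    #            K_obs      F_obs      G_obs      pcf_obs   nnd       intensity
    "lHum": [1114748.0, 0.8555850, 0.7011798, 1.356317,  9.898941, 56.0],
    "rHum": [ 967047.0, 0.8535749, 0.9122934, 1.502230,  9.237289, 61.0],
    "lFem": [1845998.0, 0.8491423, 0.9156585, 6.007650, 10.776510, 46.0],
    "rFem": [1784145.0, 0.8656865, 0.9355373, 6.342219,  8.009646, 97.0],
    "lRad": [2986224.0, 0.7896682, 0.9540846, 4.728153,  8.367454, 31.0],
    "rRad": [1136433.0, 0.7806659, 0.9162847, 4.560880,  8.964272, 22.0],
    "lTib": [1173525.0, 0.8209044, 0.9451497, 1.426124, 14.070710, 19.0],
    "rTib": [ 492396.3, 0.7658673, 0.8836768, 1.581524, 13.135290, 23.0],
}

_COLUMNS = ["K_obs", "F_obs", "G_obs", "pcf_obs", "nnd", "intensity"]


def lion_feature_table() -> pd.DataFrame:
    """The 8 x 6 reference feature matrix as a fresh DataFrame."""
    return pd.DataFrame.from_dict(_ROWS, orient="index", columns=_COLUMNS)


LION_FEATURE_TABLE = lion_feature_table()
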