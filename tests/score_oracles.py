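"""Hand-coded reference implementations of the 21 default score rules.

Each oracle is plain arithmetic over a dict of raw observation values and is
written independently of the rule engine's band/aggregation machinery; the
equivalence test drives both over grids of values straddling every cut-off.

Conventions mirrored from the engine's outputs:
count scores   -> value = number of satisfied criteria
points scores  -> value = point total
red/yellow     -> value = 2*reds + yellows, trigger = 1 red or 2 yellow
any-red        -> value = number of reds
ratio scores   -> value = the ratio
"""

from __future__ import annotations

AVPU_LEVEL = {"alert": 0, "voice": 1, "pain": 2, "unresponsive": 3}


def _cons(v):
    # altered-mentation flag, falling back to AVPU, then GCS
    if v.get("mental") is not None:
        return 1 if v["mental"] else 0
    if v.get("avpu") is not None:
        return 0 if v["avpu"] == "alert" else 1
    return 0 if v["gcs"] >= 15 else 1


def _avpu_level(v):
    return AVPU_LEVEL[v["avpu"]]


def qsofa(v):
    n = (v["rr"] >= 22) + (v["sbp"] <= 100) + (v["gcs"] < 15)
    return float(n), n >= 2


def sirs(v):
    n = (
        (v["temp"] > 38 or v["temp"] < 36)
        + (v["hr"] > 90)
        + (v["rr"] > 20 or v["paco2"] < 32)
        + (v["wbc"] > 12 or v["wbc"] < 4)
    )
    return float(n), n >= 2


def si(v):
    r = v["hr"] / v["sbp"]
    return r, r >= 0.9


def msi(v):
    arterial_mean = (v["sbp"] + 2 * v["dbp"]) / 3
    r = v["hr"] / arterial_mean
    return r, r >= 1.3


def fast_m(v):
    n = (
        (v["temp"] >= 38 or v["temp"] < 36)
        + (v["hr"] >= 120)
        + (v["rr"] >= 30)
        + (v["sbp"] <= 90)
        + _cons(v)
    )
    return float(n), n >= 1


def fast_m_red_flag(v):
    reds = (v["hr"] >= 130) + (v["rr"] >= 35) + (v["sbp"] <= 85) + _cons(v)
    return float(reds), reds >= 1


def _chart(reds, yellows):
    return float(2 * reds + yellows), (reds >= 1 or yellows >= 2)


def imews(v):
    y = r = 0
    y += 21 <= v["rr"] <= 24
    r += v["rr"] >= 25 or v["rr"] < 8
    y += (100 <= v["hr"] <= 119) + (40 <= v["hr"] <= 49)
    r += v["hr"] >= 120 or v["hr"] < 40
    y += (35.0 <= v["temp"] <= 35.9) + (38.0 <= v["temp"] <= 38.9)
    r += v["temp"] >= 39.0 or v["temp"] < 35.0
    y += (140 <= v["sbp"] <= 159) + (80 <= v["sbp"] <= 89)
    r += v["sbp"] >= 160 or v["sbp"] < 80
    y += 90 <= v["dbp"] <= 109
    r += v["dbp"] >= 110
    r += _cons(v)
    return _chart(r, y)


def meows_a(v):
    y = r = 0
    y += (35.0 <= v["temp"] <= 36.0) + (37.5 <= v["temp"] <= 38.0)
    r += (v["temp"] > 38.0) + (v["temp"] < 35.0)
    y += (150 <= v["sbp"] <= 159) + (90 <= v["sbp"] <= 100)
    r += (v["sbp"] >= 160) + (v["sbp"] < 90)
    y += 90 <= v["dbp"] <= 99
    r += v["dbp"] >= 100
    y += (100 <= v["hr"] <= 120) + (40 <= v["hr"] <= 50)
    r += (v["hr"] > 120) + (v["hr"] < 40)
    y += 21 <= v["rr"] <= 30
    r += (v["rr"] > 30) + (v["rr"] < 10)
    r += v["spo2"] < 95
    lvl = _avpu_level(v)
    y += lvl == 1
    r += lvl >= 2
    return _chart(r, y)


def meows_b(v):
    y = r = 0
    y += (35.0 <= v["temp"] <= 36.0) + (38.0 <= v["temp"] <= 38.9)
    r += (v["temp"] >= 39.0) + (v["temp"] < 35.0)
    y += (150 <= v["sbp"] <= 160) + (80 <= v["sbp"] <= 90)
    r += (v["sbp"] > 160) + (v["sbp"] < 80)
    y += (100 <= v["hr"] <= 110) + (40 <= v["hr"] <= 50)
    r += (v["hr"] > 110) + (v["hr"] < 40)
    y += 21 <= v["rr"] <= 25
    r += (v["rr"] > 25) + (v["rr"] < 10)
    y += 93 <= v["spo2"] <= 95
    r += v["spo2"] < 93
    lvl = _avpu_level(v)
    y += lvl == 1
    r += lvl >= 2
    return _chart(r, y)


def meows_c(v):
    y = r = 0
    y += (35.0 <= v["temp"] <= 36.0) + (37.5 <= v["temp"] <= 38.5)
    r += (v["temp"] > 38.5) + (v["temp"] < 35.0)
    y += (140 <= v["sbp"] <= 160) + (90 <= v["sbp"] <= 100)
    r += (v["sbp"] > 160) + (v["sbp"] < 90)
    y += 90 <= v["dbp"] <= 100
    r += v["dbp"] > 100
    y += (100 <= v["hr"] <= 115) + (40 <= v["hr"] <= 55)
    r += (v["hr"] > 115) + (v["hr"] < 40)
    y += 21 <= v["rr"] <= 28
    r += (v["rr"] > 28) + (v["rr"] < 10)
    lvl = _avpu_level(v)
    y += lvl == 1
    r += lvl >= 2
    return _chart(r, y)


def meows_d(v):
    r = 0
    r += (v["temp"] > 38.5) + (v["temp"] < 35.0)
    r += (v["sbp"] >= 160) + (v["sbp"] < 90)
    r += (v["hr"] > 120) + (v["hr"] < 40)
    r += (v["rr"] > 28) + (v["rr"] < 10)
    r += _cons(v)
    return float(r), r >= 1


def meows_e(v):
    r = 0
    r += (v["temp"] > 38.0) + (v["temp"] < 35.0)
    r += (v["sbp"] >= 160) + (v["sbp"] < 90)
    r += (v["hr"] > 120) + (v["hr"] < 40)
    r += (v["rr"] > 30) + (v["rr"] < 10)
    r += v["spo2"] < 92
    r += _avpu_level(v) >= 2
    return float(r), r >= 1


def meows_f(v):
    y = r = 0
    y += (35.0 <= v["temp"] <= 36.0) + (38.0 <= v["temp"] <= 38.9)
    r += (v["temp"] >= 39.0) + (v["temp"] < 35.0)
    y += (150 <= v["sbp"] <= 159) + (85 <= v["sbp"] <= 95)
    r += (v["sbp"] >= 160) + (v["sbp"] < 85)
    y += (105 <= v["hr"] <= 125) + (40 <= v["hr"] <= 50)
    r += (v["hr"] > 125) + (v["hr"] < 40)
    y += 22 <= v["rr"] <= 28
    r += (v["rr"] > 28) + (v["rr"] < 10)
    r += v["spo2"] < 94
    lvl = _avpu_level(v)
    y += lvl == 1
    r += lvl >= 2
    return _chart(r, y)


def mewt(v):
    n = (
        (v["temp"] >= 38.0 or v["temp"] < 36.0)
        + (v["hr"] > 110)
        + (v["rr"] > 24)
        + (v["spo2"] < 93)
        + (v["sbp"] < 85 or v["sbp"] > 160)
        + _cons(v)
    )
    return float(n), n >= 1


def sos(v):
    p = 0
    t = v["temp"]
    p += 3 if t >= 39.0 else 1 if 38.5 <= t <= 38.9 else 0
    p += 2 if t < 34.0 else 1 if 34.0 <= t <= 35.9 else 0
    h = v["hr"]
    p += (
        4 if h >= 180 else 3 if 150 <= h <= 179 else 2 if 130 <= h <= 149
        else 1 if 120 <= h <= 129 else 0
    )
    p += 4 if h < 40 else 0
    rr = v["rr"]
    p += (
        4 if rr >= 50 else 3 if 35 <= rr <= 49 else 1 if 25 <= rr <= 34
        else 0
    )
    p += 4 if rr < 6 else 2 if 6 <= rr <= 9 else 0
    s = v["sbp"]
    p += 4 if s < 70 else 3 if 70 <= s <= 79 else 2 if 80 <= s <= 89 else 0
    o = v["spo2"]
    p += 4 if o < 85 else 3 if 85 <= o <= 89 else 1 if 90 <= o <= 91 else 0
    w = v["wbc"]
    p += 4 if w >= 40.0 else 2 if 25.0 <= w <= 39.9 else 1 if 17.0 <= w <= 24.9 else 0
    p += 4 if w < 1.0 else 2 if 1.0 <= w <= 2.9 else 1 if 3.0 <= w <= 3.9 else 0
    return float(p), p >= 6


def nice_rst_pp_pa(v):
    n = (
        (v["rr"] >= 21 or v["rr"] <= 8)
        + (v["hr"] >= 91)
        + (v["sbp"] <= 100)
        + (v["lactate"] >= 2.0)
        + _cons(v)
    )
    return float(n), n >= 1


def nice_rst_p(v):
    n = (
        (v["rr"] >= 21 or v["rr"] <= 8)
        + (v["hr"] >= 110)
        + (v["sbp"] <= 100)
        + _cons(v)
    )
    return float(n), n >= 1


def msirs(v):
    n = (
        (v["temp"] > 38.0 or v["temp"] < 36.0)
        + (v["hr"] > 110)
        + (v["rr"] > 24)
        + (v["wbc"] > 15.0 or v["wbc"] < 4.0)
    )
    return float(n), n >= 2


def omqsofa(v):
    n = (v["rr"] >= 25) + (v["sbp"] <= 90) + _cons(v)
    return float(n), n >= 2


def qsofa_p(v):
    n = (v["rr"] >= 25) + (v["sbp"] < 85) + _cons(v)
    return float(n), n >= 2


def emip(v):
    n = (
        (v["temp"] >= 37.8 or v["temp"] <= 36.0)
        + (v["hr"] >= 100)
        + (v["rr"] >= 21)
    )
    return float(n), n >= 1


# --------------------------------------------------------------------------
# Per-score harness metadata: which observation fields each oracle reads and
# candidate values straddling every cut-off (±0.1 / ±0.05 around bounds).

_TEMP_FULL = [34.9, 35.0, 35.9, 36.0, 36.8, 37.4, 37.5, 38.0, 38.1, 38.5, 38.6, 38.9, 39.0, 39.5]
_AVPU = ["alert", "voice", "pain", "unresponsive"]
_MENTAL = [False, True]

ORACLES = {
    "qSOFA": (
        qsofa,
        {"rr": [14, 21.9, 22, 22.1], "sbp": [95, 99.9, 100, 100.1, 120], "gcs": [3, 14, 15]},
        {"rr": "respiratory_rate", "sbp": "systolic_bp", "gcs": "gcs"},
    ),
    "SIRS": (
        sirs,
        {
            "temp": [35.9, 36.0, 36.8, 38.0, 38.1],
            "hr": [70, 90, 90.1, 120],
            "rr": [14, 20, 20.1],
            "paco2": [28, 31.9, 32, 40],
            "wbc": [3.9, 4.0, 8, 12.0, 12.1],
        },
        {"temp": "temperature", "hr": "heart_rate", "rr": "respiratory_rate",
         "paco2": "paco2", "wbc": "wbc"},
    ),
    "SI": (
        si,
        {"hr": [60, 90, 108, 130], "sbp": [80, 100, 120]},
        {"hr": "heart_rate", "sbp": "systolic_bp"},
    ),
    "MSI": (
        msi,
        {"hr": [60, 91, 120, 160], "sbp": [90, 100, 120], "dbp": [50, 60, 80]},
        {"hr": "heart_rate", "sbp": "systolic_bp", "dbp": "diastolic_bp"},
    ),
    "FAST-M": (
        fast_m,
        {
            "temp": [35.9, 36.0, 37.0, 37.9, 38.0],
            "hr": [80, 119.9, 120, 121],
            "rr": [16, 29.9, 30, 31],
            "sbp": [85, 90, 90.1, 120],
            "mental": _MENTAL,
        },
        {"temp": "temperature", "hr": "heart_rate", "rr": "respiratory_rate",
         "sbp": "systolic_bp", "mental": "mental_state_altered"},
    ),
    "FAST-M red flag": (
        fast_m_red_flag,
        {
            "hr": [80, 129.9, 130, 131],
            "rr": [16, 34.9, 35, 36],
            "sbp": [80, 85, 85.1, 120],
            "mental": _MENTAL,
        },
        {"hr": "heart_rate", "rr": "respiratory_rate", "sbp": "systolic_bp",
         "mental": "mental_state_altered"},
    ),
    "IMEWS": (
        imews,
        {
            "rr": [7.9, 8, 14, 20.9, 21, 24, 24.9, 25],
            "hr": [39.9, 40, 49, 49.5, 70, 99.9, 100, 119, 119.5, 120],
            "temp": _TEMP_FULL,
            "sbp": [79.9, 80, 89, 89.5, 120, 139.9, 140, 159, 159.5, 160],
            "dbp": [70, 89.9, 90, 109, 109.5, 110],
            "mental": _MENTAL,
        },
        {"rr": "respiratory_rate", "hr": "heart_rate", "temp": "temperature",
         "sbp": "systolic_bp", "dbp": "diastolic_bp", "mental": "mental_state_altered"},
    ),
    "MEOWS A": (
        meows_a,
        {
            "temp": _TEMP_FULL,
            "sbp": [85, 89.9, 90, 100, 100.1, 149.9, 150, 159, 160],
            "dbp": [70, 89.9, 90, 99, 99.5, 100],
            "hr": [39.9, 40, 50, 50.5, 80, 99.9, 100, 120, 120.5],
            "rr": [9.9, 10, 14, 20.9, 21, 30, 30.5],
            "spo2": [90, 94.9, 95, 99],
            "avpu": _AVPU,
        },
        {"temp": "temperature", "sbp": "systolic_bp", "dbp": "diastolic_bp",
         "hr": "heart_rate", "rr": "respiratory_rate", "spo2": "spo2", "avpu": "avpu"},
    ),
    "MEOWS B": (
        meows_b,
        {
            "temp": _TEMP_FULL,
            "sbp": [75, 79.9, 80, 90, 90.5, 149.9, 150, 160, 160.5],
            "hr": [39.9, 40, 50, 50.5, 80, 99.9, 100, 110, 110.5],
            "rr": [9.9, 10, 14, 20.9, 21, 25, 25.5],
            "spo2": [90, 92.9, 93, 95, 95.1, 99],
            "avpu": _AVPU,
        },
        {"temp": "temperature", "sbp": "systolic_bp", "hr": "heart_rate",
         "rr": "respiratory_rate", "spo2": "spo2", "avpu": "avpu"},
    ),
    "MEOWS C": (
        meows_c,
        {
            "temp": _TEMP_FULL,
            "sbp": [85, 89.9, 90, 100, 100.5, 139.9, 140, 160, 160.5],
            "dbp": [70, 89.9, 90, 100, 100.5],
            "hr": [39.9, 40, 55, 55.5, 80, 99.9, 100, 115, 115.5],
            "rr": [9.9, 10, 14, 20.9, 21, 28, 28.5],
            "avpu": _AVPU,
        },
        {"temp": "temperature", "sbp": "systolic_bp", "dbp": "diastolic_bp",
         "hr": "heart_rate", "rr": "respiratory_rate", "avpu": "avpu"},
    ),
    "MEOWS D": (
        meows_d,
        {
            "temp": [34.9, 35.0, 37.0, 38.5, 38.6],
            "sbp": [89.9, 90, 120, 159.9, 160],
            "hr": [39.9, 40, 80, 120, 120.5],
            "rr": [9.9, 10, 14, 28, 28.5],
            "mental": _MENTAL,
        },
        {"temp": "temperature", "sbp": "systolic_bp", "hr": "heart_rate",
         "rr": "respiratory_rate", "mental": "mental_state_altered"},
    ),
    "MEOWS E": (
        meows_e,
        {
            "temp": [34.9, 35.0, 37.0, 38.0, 38.1],
            "sbp": [89.9, 90, 120, 159.9, 160],
            "hr": [39.9, 40, 80, 120, 120.5],
            "rr": [9.9, 10, 14, 30, 30.5],
            "spo2": [88, 91.9, 92, 98],
            "avpu": _AVPU,
        },
        {"temp": "temperature", "sbp": "systolic_bp", "hr": "heart_rate",
         "rr": "respiratory_rate", "spo2": "spo2", "avpu": "avpu"},
    ),
    "MEOWS F": (
        meows_f,
        {
            "temp": _TEMP_FULL,
            "sbp": [80, 84.9, 85, 95, 95.5, 149.9, 150, 159, 160],
            "hr": [39.9, 40, 50, 50.5, 80, 104.9, 105, 125, 125.5],
            "rr": [9.9, 10, 14, 21.9, 22, 28, 28.5],
            "spo2": [90, 93.9, 94, 99],
            "avpu": _AVPU,
        },
        {"temp": "temperature", "sbp": "systolic_bp", "hr": "heart_rate",
         "rr": "respiratory_rate", "spo2": "spo2", "avpu": "avpu"},
    ),
    "MEWT": (
        mewt,
        {
            "temp": [35.9, 36.0, 37.0, 37.9, 38.0],
            "hr": [80, 110, 110.5],
            "rr": [14, 24, 24.5],
            "spo2": [90, 92.9, 93, 99],
            "sbp": [80, 84.9, 85, 120, 160, 160.5],
            "mental": _MENTAL,
        },
        {"temp": "temperature", "hr": "heart_rate", "rr": "respiratory_rate",
         "spo2": "spo2", "sbp": "systolic_bp", "mental": "mental_state_altered"},
    ),
    "SOS": (
        sos,
        {
            "temp": [33.9, 34.0, 35.9, 36.0, 37.0, 38.4, 38.5, 38.9, 39.0],
            "hr": [39.9, 40, 80, 119.9, 120, 129, 130, 149, 150, 179, 180],
            "rr": [5.9, 6, 9, 9.5, 14, 24.9, 25, 34, 35, 49, 50],
            "sbp": [69.9, 70, 79, 79.5, 80, 89, 89.5, 120],
            "spo2": [84.9, 85, 89, 89.5, 90, 91, 91.5, 98],
            "wbc": [0.9, 1.0, 2.9, 3.0, 3.9, 4.0, 8, 16.9, 17.0, 24.9, 25.0, 39.9, 40.0],
        },
        {"temp": "temperature", "hr": "heart_rate", "rr": "respiratory_rate",
         "sbp": "systolic_bp", "spo2": "spo2", "wbc": "wbc"},
    ),
    "NICE-RST-PP/PA": (
        nice_rst_pp_pa,
        {
            "rr": [7.9, 8, 8.1, 14, 20.9, 21],
            "hr": [70, 90.9, 91, 120],
            "sbp": [90, 100, 100.1, 120],
            "lactate": [1.0, 1.9, 2.0, 4.0],
            "mental": _MENTAL,
        },
        {"rr": "respiratory_rate", "hr": "heart_rate", "sbp": "systolic_bp",
         "lactate": "lactate", "mental": "mental_state_altered"},
    ),
    "NICE-RST-P": (
        nice_rst_p,
        {
            "rr": [7.9, 8, 8.1, 14, 20.9, 21],
            "hr": [70, 109.9, 110, 130],
            "sbp": [90, 100, 100.1, 120],
            "mental": _MENTAL,
        },
        {"rr": "respiratory_rate", "hr": "heart_rate", "sbp": "systolic_bp",
         "mental": "mental_state_altered"},
    ),
    "mSIRS": (
        msirs,
        {
            "temp": [35.9, 36.0, 36.8, 38.0, 38.1],
            "hr": [80, 110, 110.5],
            "rr": [14, 24, 24.5],
            "wbc": [3.9, 4.0, 8, 15.0, 15.1],
        },
        {"temp": "temperature", "hr": "heart_rate", "rr": "respiratory_rate", "wbc": "wbc"},
    ),
    "OmqSOFA": (
        omqsofa,
        {"rr": [14, 24.9, 25, 26], "sbp": [85, 90, 90.1, 120], "mental": _MENTAL},
        {"rr": "respiratory_rate", "sbp": "systolic_bp", "mental": "mental_state_altered"},
    ),
    "qSOFA-P": (
        qsofa_p,
        {"rr": [14, 24.9, 25, 26], "sbp": [80, 84.9, 85, 120], "mental": _MENTAL},
        {"rr": "respiratory_rate", "sbp": "systolic_bp", "mental": "mental_state_altered"},
    ),
    "EMIP": (
        emip,
        {"temp": [35.5, 36.0, 36.1, 37.7, 37.8, 38.5], "hr": [80, 99.9, 100, 120],
         "rr": [14, 20.9, 21, 25]},
        {"temp": "temperature", "hr": "heart_rate", "rr": "respiratory_rate"},
    ),
}
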