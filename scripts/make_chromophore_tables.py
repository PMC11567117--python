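"""Generate the packaged synthetic chromophore absorption tables.

Each table is a two-column TSV (wavelength nm, absorption coefficient).
Hemoglobin tables are for whole blood at 150 g/L total hemoglobin, in 1/mm.
Bilirubin and cytochrome-c-oxidase tables are per molar concentration
(1/mm per mol/L).  Melanin and bloodless-skin baseline are analytic.

Curves are smooth PCHIP interpolants through anchor values chosen to
reproduce the qualitative structure of published compilations (Soret band,
alpha/beta bands, isosbestic crossings, NIR tails).  They are synthetic
stand-ins, not published data.

Run from the repository root:  python scripts/make_chromophore_tables.py
"""
import numpy as np
from scipy.interpolate import PchipInterpolator

GRID = np.arange(400.0, 802.0, 2.0)

# molar extinction (M^-1 cm^-1) -> mu_a of whole blood (1/mm) at 150 g/L,
# 64500 g/mol: mu_a = 2.303 * eps * (150/64500) / 10
BLOOD = 2.303 * (150.0 / 64500.0) / 10.0
MOLAR = 2.303 / 10.0  # eps -> 1/mm per M

hbo2 = [  # oxyhemoglobin, molar extinction anchors
    (400, 266000), (415, 524000), (430, 247000), (450, 63000), (470, 33000),
    (490, 23000), (500, 21000), (510, 20200), (520, 24500), (530, 39000),
    (542, 53200), (550, 45000), (560, 32600), (569, 45000), (577, 55500),
    (586, 31000), (600, 3200), (620, 1000), (650, 370), (680, 290),
    (700, 290), (730, 390), (750, 520), (800, 820),
]
hb = [  # deoxyhemoglobin
    (400, 223000), (430, 530000), (450, 62000), (470, 24000), (490, 21500),
    (500, 20800), (510, 24600), (520, 29500), (540, 47000), (555, 53500),
    (560, 53300), (576, 47000), (586, 32000), (600, 15000), (620, 7500),
    (650, 3750), (680, 2500), (700, 1800), (730, 1300), (750, 1100),
    (800, 800),
]
brub = [  # bilirubin (in situ), molar extinction
    (400, 28000), (440, 48000), (460, 53000), (480, 40000), (500, 20000),
    (520, 7000), (550, 1500), (600, 150), (650, 20), (700, 5), (750, 2),
    (800, 1),
]
cco_red = [  # reduced cytochrome-c oxidase
    (400, 50000), (420, 80000), (445, 60000), (480, 12000), (520, 5200),
    (550, 9500), (580, 7800), (605, 21000), (630, 6000), (660, 2500),
    (700, 1500), (750, 1600), (800, 2000),
]
cco_ox = [  # oxidized cytochrome-c oxidase (broad CuA band rising to NIR)
    (400, 45000), (420, 70000), (450, 30000), (480, 9000), (520, 6000),
    (550, 6500), (600, 4500), (650, 3000), (700, 2500), (750, 2800),
    (800, 3500),
]


def interp(anchors, scale):
    lam = np.array([a[0] for a in anchors], float)
    eps = np.array([a[1] for a in anchors], float)
    f = PchipInterpolator(lam, np.log(eps))
    return np.exp(f(GRID)) * scale


def write(name, mua, header):
    path = f"src/spectromics/data/chromophores/{name}.tsv"
    with open(path, "w") as fh:
        fh.write(f"# {header}\n# wavelength_nm\tmu_a\n")
        for w, v in zip(GRID, mua):
            fh.write(f"{w:.0f}\t{v:.6g}\n")


write("synthetic_hb", interp(hb, BLOOD),
      "deoxyhemoglobin, whole blood 150 g/L, 1/mm (synthetic reconstruction)")
write("synthetic_hbo2", interp(hbo2, BLOOD),
      "oxyhemoglobin, whole blood 150 g/L, 1/mm (synthetic reconstruction)")
write("synthetic_bilirubin", interp(brub, MOLAR),
      "bilirubin, 1/mm per mol/L (synthetic reconstruction)")
write("synthetic_cco_reduced", interp(cco_red, MOLAR),
      "reduced cytochrome-c oxidase, 1/mm per mol/L (synthetic reconstruction)")
write("synthetic_cco_oxidized", interp(cco_ox, MOLAR),
      "oxidized cytochrome-c oxidase, 1/mm per mol/L (synthetic reconstruction)")

# melanin: power law, 1/mm (interior of epidermal melanin, volume-fraction weighted)
mel = 66.7 * (GRID / 500.0) ** (-3.33)
write("synthetic_melanin", mel,
      "epidermal melanin, 1/mm at unit volume fraction (power-law approximation)")

# bloodless skin baseline, 1/mm
base = (0.0244 + 8.53 * np.exp(-(GRID - 154.0) / 66.2)) / 10.0
write("synthetic_baseline", base,
      "bloodless skin baseline absorption, 1/mm (exponential approximation)")

print("wrote tables;", len(GRID), "rows each")
# quick sanity: isosbestic crossings of hb-hbo2 in 500-600
d = interp(hb, BLOOD) - interp(hbo2, BLOOD)
sel = (GRID >= 500) & (GRID <= 600)
print("sign changes 500-600:", int(np.sum(np.diff(np.sign(d[sel])) != 0)))
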