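# Product-type -> legacy class mapping (eight-way scheme).
# User-overridable; unknown products fall back to "Others".
T1PKS: PKS1
transAT-PKS: PKSOther
transAT-PKS-like: PKSOther
T2PKS: PKSOther
T3PKS: PKSOther
PKS-like: PKSOther
hglE-KS: PKSOther
PpyS-KS: PKSOther
arylpolyene: PKSOther
NRPS: NRPS
NRPS-like: NRPS
NRP-metallophore: NRPS
thioamide-NRP: NRPS
CDPS: NRPS
RiPP-like: RiPP
lanthipeptide: RiPP
lanthipeptide-class-i: RiPP
lanthipeptide-class-ii: RiPP
lanthipeptide-class-iii: RiPP
lanthipeptide-class-iv: RiPP
lanthipeptide-class-v: RiPP
lassopeptide: RiPP
lassopeptides: RiPP
linaridin: RiPP
thiopeptide: RiPP
thioamitides: RiPP
sactipeptide: RiPP
ranthipeptide: RiPP
bottromycin: RiPP
microviridin: RiPP
proteusin: RiPP
cyanobactin: RiPP
glycocin: RiPP
LAP: RiPP
bacteriocin: RiPP
epipeptide: RiPP
cyclic-lactone-autoinducer: RiPP
spliceotide: RiPP
RRE-containing: RiPP
fungal-RiPP: RiPP
guanidinotides: RiPP
lipolanthine: RiPP
amglyccycl: Saccharide
oligosaccharide: Saccharide
saccharide: Saccharide
cf_saccharide: Saccharide
2dos: Saccharide
terpene: Terpene
terpene-precursor: Terpene
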