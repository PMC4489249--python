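# Default ligand blacklist: residue codes never treated as specific ligands.
# One code per line; '#' starts a comment. Override with --blacklist.

# waters
HOH
DOD
WAT

# monoatomic ions
NA
CL
K
MG
CA
ZN
MN
FE
CU
NI
CO
CD
HG
IOD
BR
F

# cryoprotectants, solvents and buffer artifacts
GOL
EDO
PEG
PG4
DMS
ACT
SO4
PO4
FMT
MPD
TRS
EPE
MES
BME
NO3
IMD
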