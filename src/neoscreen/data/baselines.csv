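analyte,median,log_sd
ALA,220.0,0.30
ARG,10.0,0.50
CIT,12.0,0.35
GLY,350.0,0.30
LEU,130.0,0.30
MET,15.0,0.40
ORN,95.0,0.35
PHE,55.0,0.19
PRO,160.0,0.30
TYR,70.0,0.40
VAL,110.0,0.30
C0,22.0,0.35
C2,25.0,0.35
C3,1.8,0.35
C3DC,0.05,0.40
C4,0.25,0.33
C4DC,0.30,0.35
C4OH,0.12,0.40
C5,0.12,0.40
C5:1,0.03,0.40
C5DC,0.10,0.40
C5OH,0.25,0.27
C6,0.06,0.40
C6DC,0.05,0.40
C8,0.08,0.42
C8:1,0.12,0.40
C10,0.10,0.45
C10:1,0.08,0.40
C10:2,0.02,0.40
C12,0.12,0.45
C12:1,0.08,0.45
C14,0.18,0.40
C14:1,0.10,0.45
C14:2,0.02,0.40
C14OH,0.02,0.40
C16,3.0,0.35
C16:1,0.15,0.40
C16OH,0.02,0.40
C16:1OH,0.03,0.40
C18,1.0,0.35
C18:1,1.3,0.35
C18:2,0.35,0.40
SA,0.8,0.35
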