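,CYS,MET,PHE,ILE,LEU,VAL,TRP,TYR,ALA,GLY,THR,SER,ASN,GLN,ASP,GLU,HIS,ARG,LYS,PRO
CYS,-0.3,-0.36,-0.23,0.0,-0.17,0.34,0.58,0.29,-1.13,-1.49,-1.23,0.17,-2.5,-0.08,-0.73,-0.6,-1.41,-1.15,-0.09,0.99
MET,-0.36,0.6,0.08,-0.36,-0.43,-0.0,1.29,0.92,-0.77,-1.24,-1.67,-1.09,-2.55,-0.57,-1.76,-1.16,-0.67,0.32,-1.24,0.3
PHE,-0.23,0.08,2.02,-0.15,-0.25,0.33,1.94,1.19,0.05,-2.42,-0.62,0.76,-1.77,-0.4,0.07,-1.44,-0.0,0.61,0.11,1.17
ILE,0.0,-0.36,-0.15,-1.11,-1.69,-0.35,1.11,0.86,-1.26,-0.36,-0.66,0.15,-2.49,-1.0,-2.72,-0.37,-0.58,-0.96,-0.47,0.8
LEU,-0.17,-0.43,-0.25,-1.69,-0.56,-1.11,0.06,0.9,-2.47,-1.36,-1.76,-0.05,-2.72,-2.1,-1.44,-1.33,-0.79,-1.12,-0.48,-0.07
VAL,0.34,-0.0,0.33,-0.35,-1.11,-0.44,0.22,0.73,-0.69,-1.73,-0.48,0.11,-1.52,0.29,-1.12,-0.33,-0.56,-0.29,-0.92,1.58
TRP,0.58,1.29,1.94,1.11,0.06,0.22,0.17,1.39,-0.43,0.13,0.43,0.56,-1.8,-0.16,-0.42,-0.37,0.25,0.4,0.11,0.07
TYR,0.29,0.92,1.19,0.86,0.9,0.73,1.39,-0.07,1.01,-0.8,0.22,1.43,-1.21,-0.07,-0.65,-0.44,-0.68,0.26,-0.34,1.56
ALA,-1.13,-0.77,0.05,-1.26,-2.47,-0.69,-0.43,1.01,-1.24,-2.35,-2.43,-1.58,-2.95,-1.41,-2.05,-0.86,-1.24,-1.76,-1.22,-0.05
GLY,-1.49,-1.24,-2.42,-0.36,-1.36,-1.73,0.13,-0.8,-2.35,-1.32,-2.26,-0.94,-3.92,-1.06,-2.32,-1.89,-1.6,-1.57,-1.28,0.71
THR,-1.23,-1.67,-0.62,-0.66,-1.76,-0.48,0.43,0.22,-2.43,-2.26,-1.96,-1.37,-1.17,-0.91,-2.5,-1.84,-2.65,-1.39,-1.49,-0.5
SER,0.17,-1.09,0.76,0.15,-0.05,0.11,0.56,1.43,-1.58,-0.94,-1.37,-0.36,-1.38,-1.48,-1.23,-1.22,-0.26,-0.71,-0.56,1.85
ASN,-2.5,-2.55,-1.77,-2.49,-2.72,-1.52,-1.8,-1.21,-2.95,-3.92,-1.17,-1.38,-4.75,-2.71,-3.16,-2.6,-2.84,-2.52,-2.53,-0.99
GLN,-0.08,-0.57,-0.4,-1.0,-2.1,0.29,-0.16,-0.07,-1.41,-1.06,-0.91,-1.48,-2.71,-0.15,-2.4,-1.03,-1.48,-0.16,-0.98,-0.59
ASP,-0.73,-1.76,0.07,-2.72,-1.44,-1.12,-0.42,-0.65,-2.05,-2.32,-2.5,-1.23,-3.16,-2.4,-1.57,-1.77,-1.56,-2.2,-1.22,-0.6
GLU,-0.6,-1.16,-1.44,-0.37,-1.33,-0.33,-0.37,-0.44,-0.86,-1.89,-1.84,-1.22,-2.6,-1.03,-1.77,-1.84,-1.31,-1.91,-0.15,-0.76
HIS,-1.41,-0.67,-0.0,-0.58,-0.79,-0.56,0.25,-0.68,-1.24,-1.6,-2.65,-0.26,-2.84,-1.48,-1.56,-1.31,-1.56,-0.62,0.47,0.22
ARG,-1.15,0.32,0.61,-0.96,-1.12,-0.29,0.4,0.26,-1.76,-1.57,-1.39,-0.71,-2.52,-0.16,-2.2,-1.91,-0.62,-0.33,-0.67,0.95
LYS,-0.09,-1.24,0.11,-0.47,-0.48,-0.92,0.11,-0.34,-1.22,-1.28,-1.49,-0.56,-2.53,-0.98,-1.22,-0.15,0.47,-0.67,0.55,1.35
PRO,0.99,0.3,1.17,0.8,-0.07,1.58,0.07,1.56,-0.05,0.71,-0.5,1.85,-0.99,-0.59,-0.6,-0.76,0.22,0.95,1.35,1.15
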