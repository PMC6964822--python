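# Default predefined substructure patterns (one SMILES per line).
# A small curated set of common functional groups and ring systems used
# when no user pattern list is supplied.
c1ccccc1
Cc1ccccc1
CCc1ccccc1
Oc1ccccc1
COc1ccccc1
Nc1ccccc1
CNc1ccccc1
Cc1ccc(O)cc1
c1ccncc1
c1ccc2ncccc2c1
c1cc[nH]c1
c1ccc2[nH]ccc2c1
Cc1c[nH]c2ccccc12
c1ccc2ccccc2c1
c1ccoc1
c1ccsc1
c1cnc[nH]1
c1cncnc1
c1ccc2OCOc2c1
CC(=O)O
CC(=O)OC
CC(=O)N
CC(=O)NC
CC(=O)C
CC=O
COC
CCO
OCCO
CCN
CCNC
CN(C)C
CC(N)C(=O)O
NC(=O)N
NC(=N)N
CC#N
C[N+](=O)[O-]
CS
CSC
CS(=O)(=O)N
CS(=O)(=O)O
OP(=O)(O)O
COP(=O)(O)O
CCl
CBr
CF
CI
Clc1ccccc1
Fc1ccccc1
OCC1OC(O)C(O)C(O)C1O
OC1CCC2CCCCC2C1
C1CCC2CCCCC2C1
CC12CCC3CCCCC3C1CCC2
CC(C)=CCC
C=CC
C#CC
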