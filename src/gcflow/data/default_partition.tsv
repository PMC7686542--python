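roi	network
vPCC_L	MTL
vPCC_R	MTL
PHC_L	MTL
PHC_R	MTL
HF_L	MTL
HF_R	MTL
DM_L	DM
DM_R	DM
dMPFC	DM
LTC_L	DM
LTC_R	DM
TPJ_L	DM
TPJ_R	DM
TP_L	DM
TP_R	DM
PCC_L	Core
PCC_R	Core
aMPFC_L	Core
aMPFC_R	Core
RMPFC_L	Core
RMPFC_R	Core
pIPL_L	Core
pIPL_R	Core
Rsp	Core
aIPL_L	FPCNA
aIPL_R	FPCNA
aDLPFC_L	FPCNA
aDLPFC_R	FPCNA
pDLPFC_L	FPCNA
pDLPFC_R	FPCNA
dmPFC_A	FPCNA
aINS_L	FPCNA
aINS_R	FPCNA
precun_A	FPCNA
preSMA_A	FPCNA
aIFS_L	FPCNB
aIFS_R	FPCNB
infFS_L	FPCNB
infFS_R	FPCNB
SPL_B_L	FPCNB
SPL_B_R	FPCNB
dPMC_L	FPCNB
dPMC_R	FPCNB
dACC_B	FPCNB
aMT_L	DAN
aMT_R	DAN
FEF_L	DAN
FEF_R	DAN
SPL7A_L	DAN
SPL7A_R	DAN
PrCv_L	DAN
PrCv_R	DAN
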