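# pvsignal drug-name dictionary: pattern<TAB>canonical, UTF-8, '#' comments.
# Patterns are cleaned (case-folded, punctuation collapsed, dose/form/salt
# tokens stripped) before lookup, so salt/dose variants of a pattern resolve
# automatically; the explicit rows below add identity entries for the
# canonical ingredient labels plus common brand-name synonyms.  Brand and
# generic forms of one ingredient collapse to a single canonical label, and
# combination products are single labels.
nitrofurantoin	nitrofurantoin
macrobid	nitrofurantoin
macrodantin	nitrofurantoin
minocycline	minocycline
minocin	minocycline
elbasvir	elbasvir
elbasvir/grazoprevir	elbasvir
zepatier	elbasvir
fluvastatin	fluvastatin
lescol	fluvastatin
mogamulizumab	mogamulizumab
poteligeo	mogamulizumab
aldesleukin	aldesleukin
proleukin	aldesleukin
interleukin-2	aldesleukin
propylthiouracil	propylthiouracil
hydralazine	hydralazine
apresoline	hydralazine
ipilimumab	ipilimumab
yervoy	ipilimumab
cemiplimab	cemiplimab
cemiplimab-rwlc	cemiplimab
libtayo	cemiplimab
albendazole	albendazole
albenza	albendazole
nivolumab	nivolumab
opdivo	nivolumab
emtricitabine	emtricitabine
emtriva	emtricitabine
metreleptin	metreleptin
myalept	metreleptin
efavirenz	efavirenz
sustiva	efavirenz
meloxicam	meloxicam
mobic	meloxicam
atezolizumab	atezolizumab
tecentriq	atezolizumab
pembrolizumab	pembrolizumab
keytruda	pembrolizumab
atorvastatin	atorvastatin
lipitor	atorvastatin
simvastatin	simvastatin
zocor	simvastatin
olmesartan	olmesartan
olmesartan medoxomil	olmesartan
benicar	olmesartan
fenofibrate	fenofibrate
tricor	fenofibrate
doxycycline	doxycycline
vibramycin	doxycycline
doryx	doxycycline
amoxicillin/clavulanic acid	amoxicillin/clavulanic acid
amoxicillin clavulanate	amoxicillin/clavulanic acid
amoxicillin and clavulanate	amoxicillin/clavulanic acid
co-amoxiclav	amoxicillin/clavulanic acid
augmentin	amoxicillin/clavulanic acid
interferon alfa-2b	interferon alfa-2b
intron a	interferon alfa-2b
ezetimibe	ezetimibe
zetia	ezetimibe
alemtuzumab	alemtuzumab
lemtrada	alemtuzumab
campath	alemtuzumab
nefazodone	nefazodone
serzone	nefazodone
cephalexin	cephalexin
cefalexin	cephalexin
keflex	cephalexin
ribavirin	ribavirin
rebetol	ribavirin
copegus	ribavirin
methylprednisolone	methylprednisolone
medrol	methylprednisolone
solu-medrol	methylprednisolone
pravastatin	pravastatin
pravachol	pravastatin
ketoprofen	ketoprofen
orudis	ketoprofen
methimazole	methimazole
thiamazole	methimazole
tapazole	methimazole
indomethacin	indomethacin
indocin	indomethacin
acitretin	acitretin
soriatane	acitretin
terbinafine	terbinafine
lamisil	terbinafine
onasemnogene abeparvovec-xioi	onasemnogene abeparvovec-xioi
onasemnogene abeparvovec	onasemnogene abeparvovec-xioi
zolgensma	onasemnogene abeparvovec-xioi
avelumab	avelumab
bavencio	avelumab
anastrozole	anastrozole
arimidex	anastrozole
darunavir	darunavir
prezista	darunavir
mesalazine	mesalazine
mesalamine	mesalazine
asacol	mesalazine
pentasa	mesalazine
lialda	mesalazine
pemetrexed	pemetrexed
alimta	pemetrexed
interferon alfa-2a	interferon alfa-2a
roferon-a	interferon alfa-2a
durvalumab	durvalumab
imfinzi	durvalumab
daclizumab	daclizumab
zinbryta	daclizumab
zenapax	daclizumab
rosuvastatin	rosuvastatin
crestor	rosuvastatin
irbesartan	irbesartan
avapro	irbesartan
bosentan	bosentan
tracleer	bosentan
lamivudine	lamivudine
epivir	lamivudine
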