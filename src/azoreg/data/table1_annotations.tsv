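# Functional annotations of the published candidate set (focal-gene profile
# neighbors in at least 5 of 50 datasets). gene <TAB> category; genes with
# multiple functions appear once per category. Reconstructed from the
# published annotation table; the "Putative/ uncharacterized proteins"
# category is complete (14 genes), other categories are a best-effort
# reconstruction of the source table's gene lists.
rsmE	Metabolic processes
yeaK	Metabolic processes
citC	Metabolic processes
cpdB	Metabolic processes
rutF	Metabolic processes
add	Metabolic processes
nfsA	Metabolic processes
nfsB	Metabolic processes
yieF	Metabolic processes
leuC	Metabolic processes
ilvA	Metabolic processes
mmuM	Metabolic processes
chaC	Metabolic processes
sdaA	Metabolic processes
trpA	Metabolic processes
dadX	Metabolic processes
cysQ	Metabolic processes
clsA	Metabolic processes
gar	Metabolic processes
lapA	Metabolic processes
lapB	Metabolic processes
lgt	Metabolic processes
tesA	Metabolic processes
fucI	Metabolic processes
manA	Metabolic processes
yedP	Metabolic processes
pgm	Metabolic processes
rbsK	Metabolic processes
rpiA	Metabolic processes
melA	Metabolic processes
galT	Metabolic processes
menB	Metabolic processes
folX	Metabolic processes
hemB	Metabolic processes
hemD	Metabolic processes
dacC	Metabolic processes
bacA	Metabolic processes
ycjG	Metabolic processes
cpdB	Cellular response
allR	Cellular response
fimB	Cellular response
gar	Cellular response
fsr	Cellular response
yohC	Cellular response
marR	Cellular response
dadX	Cellular response
marB	Cellular response
pmrD	Cellular response
iscR	Cellular response
igaA	Cellular response
pspE	Cellular response
azoR	Cellular response
fpr	Cellular response
tpx	Cellular response
hslU	Cellular response
loiP	Cellular response
hdeB	Cellular response
livK	Transport
livJ	Transport
ygiS	Transport
mdlA	Transport
mlaD	Transport
gntP	Transport
fecR	Transport
ydhC	Transport
emrB	Transport
yedA	Transport
mtfA	Transcription regulation
yijO	Transcription regulation
dcuR	Transcription regulation
cueR	Transcription regulation
iscR	Transcription regulation
phoP	Transcription regulation
tyrR	Transcription regulation
frlR	Transcription regulation
gar	Transcription regulation
allR	Transcription regulation
marR	Transcription regulation
bdcR	Transcription regulation
ybgI	Putative/ uncharacterized proteins
ybjC	Putative/ uncharacterized proteins
yidR	Putative/ uncharacterized proteins
yjeI	Putative/ uncharacterized proteins
ycjX	Putative/ uncharacterized proteins
yfjQ	Putative/ uncharacterized proteins
ybhg	Putative/ uncharacterized proteins
yggC	Putative/ uncharacterized proteins
yheU	Putative/ uncharacterized proteins
yhhN	Putative/ uncharacterized proteins
yafD	Putative/ uncharacterized proteins
yajI	Putative/ uncharacterized proteins
yjjV	Putative/ uncharacterized proteins
ypfJ	Putative/ uncharacterized proteins
fdnG	Oxidoreductase
yhbW	Oxidoreductase
yciK	Oxidoreductase
glnD	Multifunctional enzyme
holE	DNA replication
insC2	DNA recombination
insC4	DNA recombination
insC5	DNA recombination
fimB	DNA recombination
fimI	Cell adhesion and biofilm formation
yjcZ	Cell adhesion and biofilm formation
pliG	Lysozyme inhibition
ivy	Lysozyme inhibition
minC	Cell division
ybbJ	Membrane component
ypjD	Membrane component
yqfA	Membrane component
fxsA	Membrane component
yjfP	Proteolysis
dcp	Proteolysis
nlpC	Proteolysis
ydgD	Proteolysis
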