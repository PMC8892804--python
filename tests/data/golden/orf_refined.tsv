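base_accession	gene	members	cpm	aa_length	sequence
PB.1.1	GENA	PB.1.1|PB.1.2	340.0	389	MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGLGRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGGSLGSPLRPLLLSARPPWSVVLPASRRSLGRGSPSPLPVSGVRFSGLFPSAFGAALRLSVRLCCRVFASARPSPRCGRVPAVARRCPVVPFGVCCCPRLRAPAFLLAGFSCWGGLAPPLPFLWLCFLLARGGAPFCAGACSLAALGCVAAGCRGPLLLPRAVRRMAWGCGVLWVLLPWVLAVACSCGSPAGGPLCPGGSVVGVGAPWGAFFLWPVSCAGVGASSSLPRAVAFPGLPRRVLCRLVGCGVVGLFCSLLPPAFSGWCLPWAAS
PB.1.3	GENA	PB.1.3	4.0	300	MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGLGRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGGSLGSPLRPLLLSARPPWSVVLPASRRSLGRGSPSPLPVSGVRFSGLFPSAFGAALRLSVRLCCRVFASARPSPRCGRVPAVARRCPVVPFGVCCCPRLRAPAFLLAGFSCWGVGAPWGAFFLWPVSCAGVGASSSLPRAVAFPGLPRRVLCRLVGCGVVGLFCSLLPPAFSGWCLPWAAS
PB.1.4	GENA	PB.1.4	80.0	425	MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGLGRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGGSLGSPLRPLLLSARPPWSVVLPASRRSLGRGSPSPLPVSGVRFSGLFPSAFGAALRLSVRLCCRVFASARPSPRCGRVPAVARRCPVVPFGVCCCPRLRAPAFLLAGFSCWLVVRFCFWVVSVSSFVPVRFLCGVAGVWWRSRARFRGGLAPPLPFLWLCFLLARGGAPFCAGACSLAALGCVAAGCRGPLLLPRAVRRMAWGCGVLWVLLPWVLAVACSCGSPAGGPLCPGGSVVGVGAPWGAFFLWPVSCAGVGASSSLPRAVAFPGLPRRVLCRLVGCGVVGLFCSLLPPAFSGWCLPWAAS
PB.2.1	GENB	PB.2.1	95.0	338	MLFGPSALSCVRPPSPRPFCGRRSGPARLRSVPGSVPRRGVVFRRACAFGAVPSCPVWPLLLPLRVVSVRLGGPPSFFPWCPRGSLVLAAGLAFLLLSSAGLAPPCPARAVRMRASPVLPSPRVACFLCFLLGAFGSVPALWSGPPVGPSCCACAFGAPVRGASGGCLRVGPLAVSPWVSALLVFLVRGPPPRSSPLACSVSAFCLGSPRSVRLRMRGAGWRPGVVLPVFSVLAAVSRAFSGPGLVPWLVRRGPRPACAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCSSVGWGFLFFAFSPSVSVFPCVLGLRGLGLCCLGLLVAS
PB.2.2	GENB	PB.2.2	5.0	253	MLFGPSALSCVRPPSPRPFCGRRSGPARLRSVPGSVPRRGVVFRRACAFGAVPSCPVWPLLLPLRVVSVRLGGPPSFFPWCPRGSLVLAAGLAFLLLSSAGLAPPCPARAVRMRASPVLPSPRVACVRLRMRGAGWRPGVVLPVFSVLAAVSRAFSGPGLVPWLVRRGPRPACAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCSSVGWGFLFFAFSPSVSVFPCVLGLRGLGLCCLGLLVAS
PB.2.3	GENB	PB.2.3	60.0	141	MRASPVLPSPRVACVRLRMRGAGWRPGVVLPVFSVLAAVSRAFSGPGLVPWLVRRGPRPACAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCSSVGWGFLFFAFSPSVSVFPCVLGLRGLGLCCLGLLVAS
PB.2.4	GENB	PB.2.4	10.0	123	MRGAGWRPGVVLPVFSVLAAVSRAFSGPGLVPWLVRRGPRPACAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCSSVGWGFLFFAFSPSVSVFPCVLGLRGLGLCCLGLLVAS
PB.3.1	GENC	PB.3.1	120.0	395	MSCSFSGRGGVLGLGPPAGWALSPWPCWFSLLSVASVVPCCGASFALPLVFGASLLGLGRGLVLGALSWLSRSRSRRLCLPRFGVPFSAAVVPGLRVLVRPRRFGFVVGVFGVRVAWASPPFCLVWPGVRCGAPSAVCALRMVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAALRRCPGACRAGGVRVLLRFVSLPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGAFALRGRGVAGRFSCFSGCSRWFFGARLLAGRAGCALRCLWGAFVFGLLGPPPAVPRCRMSPLVRGFLSPPVCVVVLSLLLSRSRLGPVPRLLSAARVSVPSVLLLRAAFSVVLCPVPCSLFRPRAVWFPRPCPGCWVLRSFRSSGVSGRCVSCVL
PB.3.2	GENC	PB.3.2	50.0	254	MVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAALRRCPGACRAGGVRVLLRFVSLPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGAFALRGRGVAGRFSCFSGCSRWFFGARLLAGRAGCALRCLWGAFVFGLLGPPPAVPRCRMSPLVRGFLSPPVCVVVLSLLLSRSRLGPVPRLLSAARVSVPSVLLLRAAFSVVLCPVPCSLFRPRAVWFPRPCPGCWVLRSFRSSGVSGRCVSCVL
PB.3.3	GENC	PB.3.3	4.0	311	MSCSFSGRGGVLGLGPPAGWALSPWPCWFSLLSVASVVPCCGASFALPLVFGASLLGLGRGLVLGALSWLSRSRSRRLCLPRFGVPFSAAVVPGLRVLVRPRRFGFVVGVFGVRVAWASPPFCLVWPGVRCGAPSAVCALRMVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAALRRCPGACRAGGVRVLLRFVSLPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGAFALRGRGVAGRRVSVPSVLLLRAAFSVVLCPVPCSLFRPRAVWFPRPCPGCWVLRSFRSSGVSGRCVSCVL
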