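>GENA|PB.1.1|pFSM|340.0
MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGL
GRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGG
SLGSPLRPLLLSARPPWSVVLPASRRSLGRGSPSPLPVSGVRFSGLFPSAFGAALRLSVR
LCCRVFASARPSPRCGRVPAVARRCPVVPFGVCCCPRLRAPAFLLAGFSCWGGLAPPLPF
LWLCFLLARGGAPFCAGACSLAALGCVAAGCRGPLLLPRAVRRMAWGCGVLWVLLPWVLA
VACSCGSPAGGPLCPGGSVVGVGAPWGAFFLWPVSCAGVGASSSLPRAVAFPGLPRRVLC
RLVGCGVVGLFCSLLPPAFSGWCLPWAAS
>GENA|PB.1.3|pNNC|4.0
MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGL
GRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGG
SLGSPLRPLLLSARPPWSVVLPASRRSLGRGSPSPLPVSGVRFSGLFPSAFGAALRLSVR
LCCRVFASARPSPRCGRVPAVARRCPVVPFGVCCCPRLRAPAFLLAGFSCWGVGAPWGAF
FLWPVSCAGVGASSSLPRAVAFPGLPRRVLCRLVGCGVVGLFCSLLPPAFSGWCLPWAAS
>GENA|PB.1.4|pNIC|80.0
MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGL
GRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGG
SLGSPLRPLLLSARPPWSVVLPASRRSLGRGSPSPLPVSGVRFSGLFPSAFGAALRLSVR
LCCRVFASARPSPRCGRVPAVARRCPVVPFGVCCCPRLRAPAFLLAGFSCWLVVRFCFWV
VSVSSFVPVRFLCGVAGVWWRSRARFRGGLAPPLPFLWLCFLLARGGAPFCAGACSLAAL
GCVAAGCRGPLLLPRAVRRMAWGCGVLWVLLPWVLAVACSCGSPAGGPLCPGGSVVGVGA
PWGAFFLWPVSCAGVGASSSLPRAVAFPGLPRRVLCRLVGCGVVGLFCSLLPPAFSGWCL
PWAAS
>GENB|PB.2.1|pFSM|95.0
MLFGPSALSCVRPPSPRPFCGRRSGPARLRSVPGSVPRRGVVFRRACAFGAVPSCPVWPL
LLPLRVVSVRLGGPPSFFPWCPRGSLVLAAGLAFLLLSSAGLAPPCPARAVRMRASPVLP
SPRVACFLCFLLGAFGSVPALWSGPPVGPSCCACAFGAPVRGASGGCLRVGPLAVSPWVS
ALLVFLVRGPPPRSSPLACSVSAFCLGSPRSVRLRMRGAGWRPGVVLPVFSVLAAVSRAF
SGPGLVPWLVRRGPRPACAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCS
SVGWGFLFFAFSPSVSVFPCVLGLRGLGLCCLGLLVAS
>GENB|PB.2.2|pFSM|5.0
MLFGPSALSCVRPPSPRPFCGRRSGPARLRSVPGSVPRRGVVFRRACAFGAVPSCPVWPL
LLPLRVVSVRLGGPPSFFPWCPRGSLVLAAGLAFLLLSSAGLAPPCPARAVRMRASPVLP
SPRVACVRLRMRGAGWRPGVVLPVFSVLAAVSRAFSGPGLVPWLVRRGPRPACAGAVARS
CRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCSSVGWGFLFFAFSPSVSVFPCVLGLR
GLGLCCLGLLVAS
>GENB|PB.2.3|pNIC|60.0
MRASPVLPSPRVACVRLRMRGAGWRPGVVLPVFSVLAAVSRAFSGPGLVPWLVRRGPRPA
CAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCSSVGWGFLFFAFSPSVSV
FPCVLGLRGLGLCCLGLLVAS
>GENC|PB.3.1|pFSM|120.0
MSCSFSGRGGVLGLGPPAGWALSPWPCWFSLLSVASVVPCCGASFALPLVFGASLLGLGR
GLVLGALSWLSRSRSRRLCLPRFGVPFSAAVVPGLRVLVRPRRFGFVVGVFGVRVAWASP
PFCLVWPGVRCGAPSAVCALRMVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAA
LRRCPGACRAGGVRVLLRFVSLPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGA
FALRGRGVAGRFSCFSGCSRWFFGARLLAGRAGCALRCLWGAFVFGLLGPPPAVPRCRMS
PLVRGFLSPPVCVVVLSLLLSRSRLGPVPRLLSAARVSVPSVLLLRAAFSVVLCPVPCSL
FRPRAVWFPRPCPGCWVLRSFRSSGVSGRCVSCVL
>GENC|PB.3.2|pFSM|50.0
MVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAALRRCPGACRAGGVRVLLRFVS
LPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGAFALRGRGVAGRFSCFSGCSRW
FFGARLLAGRAGCALRCLWGAFVFGLLGPPPAVPRCRMSPLVRGFLSPPVCVVVLSLLLS
RSRLGPVPRLLSAARVSVPSVLLLRAAFSVVLCPVPCSLFRPRAVWFPRPCPGCWVLRSF
RSSGVSGRCVSCVL
>GENC|PB.3.3|pNNC|4.0
MSCSFSGRGGVLGLGPPAGWALSPWPCWFSLLSVASVVPCCGASFALPLVFGASLLGLGR
GLVLGALSWLSRSRSRRLCLPRFGVPFSAAVVPGLRVLVRPRRFGFVVGVFGVRVAWASP
PFCLVWPGVRCGAPSAVCALRMVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAA
LRRCPGACRAGGVRVLLRFVSLPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGA
FALRGRGVAGRRVSVPSVLLLRAAFSVVLCPVPCSLFRPRAVWFPRPCPGCWVLRSFRSS
GVSGRCVSCVL
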