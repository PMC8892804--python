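>GENA|GENA-201|reference|0.0
MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGL
GRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGG
SLGSPLRPLLLSARPPWSVVLPASRRSLGRGSPSPLPVSGVRFSGLFPSAFGAALRLSVR
LCCRVFASARPSPRCGRVPAVARRCPVVPFGVCCCPRLRAPAFLLAGFSCWGGLAPPLPF
LWLCFLLARGGAPFCAGACSLAALGCVAAGCRGPLLLPRAVRRMAWGCGVLWVLLPWVLA
VACSCGSPAGGPLCPGGSVVGVGAPWGAFFLWPVSCAGVGASSSLPRAVAFPGLPRRVLC
RLVGCGVVGLFCSLLPPAFSGWCLPWAAS
>GENA|GENA-202|reference|0.0
MPPLPLVALWSGFVRGSLSSPLSGCASPGPPGSSFPAWLVVAWSAARGLGSSSAARLLGL
GRWPAFCRMLFAGRCRLASVAWASSVGSLVASSFASLGRGGRGRFSCSFSVCSRPSGRGG
SLGSPLRPLLLSARPPWSVVLPASRRSLGRGGLAPPLPFLWLCFLLARGGAPFCAGACSL
AALGCVAAGCRGPLLLPRAVRRMAWGCGVLWVLLPWVLAVACSCGSPAGGPLCPGGSVVG
VGAPWGAFFLWPVSCAGVGASSSLPRAVAFPGLPRRVLCRLVGCGVVGLFCSLLPPAFSG
WCLPWAAS
>GENB|GENB-201|reference|0.0
MLFGPSALSCVRPPSPRPFCGRRSGPARLRSVPGSVPRRGVVFRRACAFGAVPSCPVWPL
LLPLRVVSVRLGGPPSFFPWCPRGSLVLAAGLAFLLLSSAGLAPPCPARAVRMRASPVLP
SPRVACFLCFLLGAFGSVPALWSGPPVGPSCCACAFGAPVRGASGGCLRVGPLAVSPWVS
ALLVFLVRGPPPRSSPLACSVSAFCLGSPRSVRLRMRGAGWRPGVVLPVFSVLAAVSRAF
SGPGLVPWLVRRGPRPACAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCS
SVGWGFLFFAFSPSVSVFPCVLGLRGLGLCCLGLLVAS
>GENB|GENB-202|reference|0.0
MLFGPSALSCVRPPSPRPFCGRRSGPARLRSVPGSVPRRGVVFRRACAFGAVPSCPVWPL
LLPLRVVSVRLGGPPSFFPWCPRGSLVLAAGLAFLLLSSAGLAPPCPARAVRMRASPVLP
SPRVACVRLRMRGAGWRPGVVLPVFSVLAAVSRAFSGPGLVPWLVRRGPRPACAGAVARS
CRVSRSRVPVPCVRSSRFLPAVLGRLVLGGFSRCSSVGWGFLFFAFSPSVSVFPCVLGLR
GLGLCCLGLLVAS
>GENB|GENB-203|reference|0.0
MRASPVLPSPRVACFLCFLLGAFGSVPALWSGPPVGPSCCACAFGAPVRGASGGCLRVGP
LAVSPWVSALLVFLVRGPPPRSSPLACSVSAFCLGSPRSVRLRMRGAGWRPGVVLPVFSV
LAAVSRAFSGPGLVPWLVRRGPRPACAGAVARSCRVSRSRVPVPCVRSSRFLPAVLGRLV
LGGFSRCSSVGWGFLFFAFSPSVSVFPCVLGLRGLGLCCLGLLVAS
>GENC|GENC-201|reference|0.0
MSCSFSGRGGVLGLGPPAGWALSPWPCWFSLLSVASVVPCCGASFALPLVFGASLLGLGR
GLVLGALSWLSRSRSRRLCLPRFGVPFSAAVVPGLRVLVRPRRFGFVVGVFGVRVAWASP
PFCLVWPGVRCGAPSAVCALRMVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAA
LRRCPGACRAGGVRVLLRFVSLPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGA
FALRGRGVAGRFSCFSGCSRWFFGARLLAGRAGCALRCLWGAFVFGLLGPPPAVPRCRMS
PLVRGFLSPPVCVVVLSLLLSRSRLGPVPRLLSAARVSVPSVLLLRAAFSVVLCPVPCSL
FRPRAVWFPRPCPGCWVLRSFRSSGVSGRCVSCVL
>GENC|GENC-202|reference|0.0
MSCSFSGRGGVLGLGPPAGWALSPWPCWFSLLSVASVVPCCGASFALPLVFGASLLGLGR
GLVLGALSWLSRSRSRRLCLPRFGVPFSAAVVPGLRVLVRPRRFGFVVGVFGVRVAWASP
PFCLVWPGVRCGAPSAVCALRMVGGGVPRFLCGPVSRCGCVLLRFSCFSGCSRWFFGARL
LAGRAGCALRCLWGAFVFGLLGPPPAVPRCRMSPLVRGFLSPPVCVVVLSLLLSRSRLGP
VPRLLSAARVSVPSVLLLRAAFSVVLCPVPCSLFRPRAVWFPRPCPGCWVLRSFRSSGVS
GRCVSCVL
>GENC|GENC-203|reference|0.0
MVGGGVPRFLCGPVSRCGCVLLRCSPPVRCFRVLWALAALRRCPGACRAGGVRVLLRFVS
LPAWGFRLPGCCVLCSFWPRLARVRWCPRVCGFVALAGAFALRGRGVAGRFSCFSGCSRW
FFGARLLAGRAGCALRCLWGAFVFGLLGPPPAVPRCRMSPLVRGFLSPPVCVVVLSLLLS
RSRLGPVPRLLSAARVSVPSVLLLRAAFSVVLCPVPCSLFRPRAVWFPRPCPGCWVLRSF
RSSGVSGRCVSCVL
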