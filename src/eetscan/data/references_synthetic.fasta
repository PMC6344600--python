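>MtrA_synth
MKFWVWMFMAIFASLYTTKAGNLAFAVEQDKCVECHSASRTAKYATTLLLQARLENKHEL
FAAIAGIYPTNPNNCKPCHVTINPITQPGSRVKYDAYVEKECEGCHIILILQYQLKDITL
CQKCHVYFIVEVLEVEVSVMGFQRLKELGYALLPNAAALMSGLAVCLPCHSTVGSSHQGV
ARQQIAGEEMGTTLGFCLRCHLALVFPTLWELLVEIASGYCRPCHSTPTGFVKWSIKLLL
SCKKCHEVAWEKKDSLYDLTTPSFGYIGISVGAVSLDKLPDGCVPCHDILPVPPSSEMGL
PCSRCHGHGLGLSANEGDKERWSQFAVPKKTCN
>MtoA_synth
MRKMLFVVWAVLAWDRPYSTMPIDKNFALDKFCSLCHAQAGTLIPTISIIITSDRIAVEE
AGIVDPLIKYDTCTKCHGENATTQQPWGYNGAEFCHSCRYCHYAVKHSDLKCALCHVISG
AKTGAGESATRIIYLFTMKVELMTCAPCHLEGLTLKAFYEEKELEAICPNCHVDIGKPPT
SIGVIPATDKIFSCNLCHLYRAIAILIVDNNRRSIKLQVFLDLCQTCHYLKDIGIVEKMG
GFVIVTCEKCHVRTRAFNKKGLEPMAIGPNLKCVPCHTQKNEATRMSNGIALTLEAAPDR
YGNDMFNKTN
>PioA_synth
MRKAMMILWFIAMAKKTSRAGRLIEVSSYKFCLQCHPSETGKKLTEIAERRIDADGSAPK
VCRNCHRPMGEEWDLLEVKSTKAGDRLVKAAGTELTASYKYIEAESYLYCVYCHVAKSEE
GYIELGIDGSRQEFESGLSGCDECHYLTAFVDGNFTSKFENDTLDLVVGQQIPLQICFGC
HADAANPRLIGINSNRLDRRLVACYQCHQVEPKKTQVDICNNCHVRPGSQDRLMLNSGGF
QNAKNLAAEADNTGLSNSTLKEGLCKACHERSKWASFLEVKPEGDLRSMGNKTPIILYPA
LCRRCHKRSCRLCHRVMEEGLKREKFGGGQQIGVYNEVYAALPSY
>OmaB_synth
MKWVILALFMIALTKVATGIGSTNFSGERMETYERVEFFKCYACHVSNNAEKILRAWSNS
AGHQYDDPHYYADGTSVEAYELALELMCLGCHPKMGATTNSVTYGDNSGGNDIARCNSCH
QALITDNECGNCHSSLLQGQGPMRREPRMIQAGSLARQVYIFDSGAHLRPACDQCHTGIT
RNGEILASSMSAIGQWFPEKECRDMTNDRISGIDEYCSGCHGKEQDIAITESSLYFGVQP
WVVEVICALCHTPTNLNVRTNLFRKGLPIALELAGSKSLLKNLRTCFTCHARDDSGVMNA
>MtrB_synth
MRKVWFVLLFAAGQLNGLDDDRTRKNIDACLFQMLLYTESLDTPSEPGIWLRKDASQLEG
IVQFRTGSQPPEGQTKNEALKDMDGLIVNGMLIAGGKITGSSEPGMQLMSRQDTEFENIS
AMGYEGEESQGGFNWAVYQMIDRAVGIQGTDKKRPSTVPALQSALWKAKKDIAPGSPVMT
LQGDQLIAIRIVKINLVEIKTGREAMEFWLVKDKDVRRVRTFTKRDYDLNGLLDWMDLIV
IRNRSRIYPEIEEVMPFVGPEGRTSLDAMEFLRKLTGIVPEWAEYALLKRMKSYVGRLTL
EFMVIREALVNFMTTGLALGREFLLKIETLGYMNDEYNVTPAAGDMASTVAWLTTEAIAI
APAVESVPRVTVRGRIDPEGARLLLMSDLKGVLGMMIGWGSVEVKTTARLISMIIDTITG
LASANKKLELDLMGEEQAENRNPLTSTEKGGPAQEKPVMLTVASVSIDLLAADSLLVIKY
GGTDVVWQASLVNVLLQVSKIPTADDSRSRTERILALDPEGFMEVGPGDTNRNTVYWKAA
INVKAGDSVVTNSSATGKLNPKKVESFTFVDQIRKVVSGEARSYDLKPLADAKQISMMKS
GRDKGVEKVLGYLRDSLSNLIRTLWATIVELVDLYAIREIFTVVGADTANRTEVAEAYVN
VAESEILSGLGQVLAKCGPS
>MtoB_synth
MRVVVIWWFFVMAPSFLKDNDGEKSQWVMFKVTFATLPALFVSTLRLSLSLIVSSEQVNF
ATIFLANPHTVHVFIAWKYIAKDTWFNATLQRNLGLAEKHEGKSQSRTNIVDPLKLRVEA
DKAFVLLVLKLASTGKLRVSKGKTYITTIAEDIQLFPYAEKAMPEKGEITRMNVQGMQMR
LSEGILFIATDWSIAQQKRFLSGSVQTRLGLDPGKFYEESTTWKSFSDELVAAAMAAWRL
ATIEPPVTTLYSAAGPKWSKIGLQRLNHVTLIAEMQDFEAYLYQSPDADDPIGPALMGKN
GVWSETMLFHKQPRKAQNFYAAAINDQMRDIDALYFGERVSKDTSEFSFQSLQVVAPVPV
DQMTMMNSMKRAMNSRPTRGKFKALKLYLPGLIRDAAATPMVGSNRSDRVFTLELAFSGA
VQDVRGIWYNQTATPKVMSADRAWVVRMMIAARDPGQQIGSKMGQFENIFALIPAQQNVM
QQVLSAMRGAVSGKEFNSQNVGTSVDAYDGLKAVYTKTPLGAKDASESLVNRTFLVIPNK
GRQDRQMFRVKIGVEVLAERMQPAVLAPMAPEIDENHQMTRGQTIRPAQRDLFTPAKQYD
GKGIIVTSLDYSVADTCILTGGPFEPKHLALDARDTGVFMSAVEIDLILTSKAPDIESKE
FDEEMIVSDTGDGIIWFAKEYAANIEDRRYPELTPKAKDPLYMRQTSTKLTLTKKGDEAG
EIKAGMTTLFSYLIARMASLKQTTISWHVASETGTGFKGH
>PioB_synth
MRKFAMWVVMAFLATRAEMVFMYAADLWRLQEDAGICANRGNRSPSLVVAREIRSELLPT
TIKGGLTPNLTSAVIRGTSINCRRGTASQLKMQFIDMSDAYTQEIEEGHFALMGEIPASV
AKPRMGKIPVLKKAFCAKLETDYKEQQILLEVMYRAGVAELDFIIAGFSPDGKALDPRVY
TRDWSQVARPWPLDLQSLEFYYRAEFGKVGKDKIIMRNAAQKLYGAEKMQQSAYKILSAL
QNACLEDVVQDPKKDMLQHPYLVHEPMDTQASVSSLIALRLSDQPIVMGLNLPVPPQLPR
LEAGPRLLTSNQAIDEINDKQDKLFLKVYALVPSLDFSKTRPSVRSSANEATVIFTKMQQ
IANDGWRLSGKDKRLEQEGQHRDTLTSGEGEPNDTGQLPQVASGKKVISITPLSPTIYVF
DTGIARTEYIIKTCEWLRTFLSNPVMAETRGPYAAWEVNLTQQFFLAKQAGESRDSVVVS
KLMRAKLKSGGIAADGHVSNSPAHDLQLLLAYPFSRVCLPIFWQERALLLTIVYGAEPGG
>OmbB_synth
MKFVVMMWIVMFAQLAVYAGLVVKPFGSFLLKVTLTYALALVNRELHGTDAEYVTIVEAS
SFQPKYVREELYYYADIFQTFVRMFVNFFIAFFTERITYKRKEEMGGWAKLAAFSIGRGA
DKTVPQELYTKAGDARWDDLAWVANLRFTLISQQPGFRFRQILLLTKSRRLLIDGAGLWP
NDVASGIQNYICDEFVKKLTIGFAGSLEKEIRRFATQRPGALLVQLYKRQILPLGLAASA
RRKNADLALVGDKLVLKYLLSTKEYEQNTTAGLLRLDLQHSTLKGEMRRTKRVLNLEQAV
ETMVPELDVAFIPNHVFGRGEIVDVLTPGAFSVETPNMGCSTFDTTNIYTLELMLASADT
SLTSLKNVAGTWQETKVRFIGDLLKQGIWGSKNELRIPDKILDTAYDVYEPAALLHSLAT
LLLIEPRGNAIGNLGRINMGIFNIGLKGARAAGVDKVALLIGTFNHAASLSANAERPVVL
LFAFTYEHEELLKDIGSITEPSAVIQIARGHKTLILVSLQSQALDGNGMNAKGVTAQVVV
GEPRANLITPGQWQFYVETSDVAQGFQTSVESKVDLYSWKFLELTLSIMAFASVISSLYA
IAKAWSLGIPQLENTAMGKLEFANGGGVNSKARLNVLLNPQERILTLRGKEGFTVIDETM
ISASQTEVKTLEPGLKAALRVMSEIAADQTGDTGENPLRIGPRASRDGGPTSKQGTVRDV
>porin_other_synth
MKVVWLLWMLIAGGYLGARVSKLQDISLVGALYLTMTWLGKEETLTGSELPQYGDSTDLR
DRLAASEAGVIQIREGVGPRGEYVESAVQRWMDFVNYETGESNERLGRLAFEGRAPTTST
ITVLLLVDKGLGAQVSNVISQMFKDLGGATPATTGRLENQDARFIDGLQTLDLRALGVNR
AAVEIFLDEGASVWPNEDFRSPVNLNLSKAVMRLASTMVPTRSSDYQSDGNGGAQVLVRD
PYVAGSSSQQSSMLRQPFMELDTKKTKRRRLSARRIEVRSDRLNLERLRITVTFTYALLL
VELPLQLATVVLGEARELIFIKFEYTEYSEATRPGDVYAVSAVFTGIIDWKFSNYKNLWR
SETKLRDMYDYKGVNLTVGPIANYASVEIDVYAFLLGPKR
>MtrC_synth
MKIAFIFLFVAGTVWMGPRSADRLAQPKSLDVEFFRAMKNSNRKIECYGCHLMYILQGEI
LQARLIMASTISLEGSRSIAPNDLLPLVRLCTDCHAIKTDLRRKEQWNTLLSLRQGQQSG
SASKHTLGFMRLSSGVSRAQKTLERLIQNTNETTWAGSQLRKKDGSRKDEALCVTCHSGD
LGDAATSKGVVFAASFVASSFDLTPIAMAARYRKNCANCHRNLGGQLALLDKGTRMLSTP
NGAADGGTSTNFEKGTALNPIIDRDPKESEMDGMELFENLRAAKNRRRAPFYNEVRLSGG
KLMVPQNAVWANRDASLCVYCHQSVDINKPYVVNNRSKSRAPACYGCHVVATMAREPLNR
FHSVYTEIAKKRRNSQSSVAGPKQGGFTVEYKPQMRNFCNLCHGIVTTGADVSLLSPTMN
PSEDMEASGAPHEILVSPVVYIQTYASTLEETKGQGLVIAVLIVIQPKNPKRNEANNKGE
WYCQKCHSYVKLDIFMINIFKAAKAATGLNAREGKKKYTRARIANQIPNSWVCQFCHTDQ
NTFLDSFIGKTRFGYRSQSFGSKRGDSSTNGPPAPRRPEIIYIGISYIDPFEKLIANKDP
VGKSYTVCRLCHAIWSKTLTRNMPEDPLFYLKTRPYIIEDGRIEGSYVFD
>OmcB_synth
MKFFWLAMILAIVVTPWFFGSGSRKPVQARAYFIPVEGAPSQNSVLYSVSYLVEVPTFLE
AIAEESMTFRCTECHGRAPSFIKIVDINDPSRTGSSQNGVTRLNPTEVDFLFDVRFELRP
ELTKGLCSVCHVAELNGALTHGTNREIADVNRSKFNLSKRDLLTLSRDCSNCHIAVDRVD
YPGSIADELVPTKNPQLPLHRGRVVLRVFCLECHAFPLVSMMVLNLLMYSMGDAGITKNQ
AVIDRRKGESVEQIGGHLLRLKYVVGLNGIVGLNCSLCHDKWIETAFQSPEFKSTNVKLT
ISDAAVRWFARDGDDAAIRIDTEGGAGDGAISDRSAGEAADIPKIQLALFCEPCHTGFMT
FNTDGMALAIFRTRTSAKTFIFEKKRMFLSCKNCHYGKYMARPLLIVLSKEEIREPVGIA
IYVELFHPEMFADCNRCHALGRKINLGIEKLLKSPLEEISGNTLADTLLVVGEMPLAGGS
GDLQGPAVERRSISRRRSRAPLEEPRIPSRLQCSLCHRNAFFRLKLDAKLEYIICLSCHY
KWRSGQDDFKTGKNYPPYAGMFSFPVQTAIGDRLIQSAACVQCHQLTALLQAVGLKLNQF
NKMRQGDTAQPIDKEPMVEEYMRIDLRKMLNADESLDSRLCFQCHPYYGTRGLGRLNPVR
IKRSNIAFSAYRRTKLFNGANEKNVGRRDRSENFLKPTDQ
>OmcE_synth
MRRVMLMIFIAFMVAVDTMSGVSAVVDRGAKIVVKGGGSNCPPCHFVKSSRNGFGAERRK
FYSMLEGNSDILPAVLRPSNKELWLSMEEWCNLCHGDTSEHPVYPSQVDKKGADNVDKDD
CSKCHSGRTKPMVYNQVPMDEGIEQKQEGDDFECPKCHKLTSIRVVYTKATLAKAGDKRL
>OmcS_synth
MKVVFIVWFVWAARPEPRTNRKLPVSRANCRPCHMVIALVFGWDADPPGGETAHRIVFGG
ELTVAIHRLEYRVIVYITTGIRPAEERFSGEQKKTGDSAYMAGFLEDADGANFFIIRQVA
MPQELTYQTSQVRLNITLCPPCHISPAAPGNALSSFDSIPMTAGENARIILTFQNERSNQ
TVLYSEKYSRLAVPASTEDLMEPATKDRDSDLTELNPRRCETCHNQADDCPSCHPSANPS
AEMTTYKSATTGGKLKDILLQSGGRMKEYRDQRRELPRRTALPIDLLPIQVFVVQTVPAL
FKCQYCHKADRSEDLIILGQGLLTLTATEFVRGGTCGVCTKGRPRLLSAGAWDTLHKKAA
PRGIVLFAKGLNQDLGRNLYTDERCVLAEEQLYKVCQDCHQPNRETLMSSKLGIGRLTSA
KDSTMGQDYK
>OmcZ_synth
MRRLIFLLIAAWVALMGGKLSPLQLDPLGLPAPIEELAGALNEELSKIPDPKVSQTKHSF
RWVIRDVPIEPAGDLERGCYNCHFMERRPNYGINGVCVYFGTPLPIGEPRELTGVISKKW
FVLARIGLNESLMCGPCHSPSQTYNTQNEGRKCKDCHKAYRAASSEEGEGETRDNGRILD
YGFGNTVSAPAAKGLPLYLVGSGKTINIGVITSKNRSKGRIWPGVVNPVIGCSACHPKDF
AQQVVGGLPLTYKWQGILWRSRNDIIAVCRSCHRAIGGFPNLISDVNEATQAPEVLDADE
SKTLDLNRWTPSSKYEGNLVDQWRAEIEIGGVDLAHGPEVRACSPCHRVQFQSEGAVKGT
CFYCHNNWPNGFSKKDLMLPTMFGFSEKLSNLIFVKRQIAPILPYLPFIPVHVQLEAIMG
GVSAACRPCHQPQKVPGMEQTLVSMDEQNAMRLNFQPGPRMGKQQADIFAARINSRAGLP
>Cyc2_synth
MKVAMMIVAWIAYLPQNNQSLANEKDYVPSGCYLCHKSVIKGLETTFLIGSEQTSKVGSP
PAQYVWAMEAEAGIATAVVIAKYNLTKLKSGRELENVIGDTLNVGRILGTIDPETRILGK
AQITKREKRELNVLSVYKMLAANDQVDELFVLIFGEMANYIVKGSWVLETTEKAADDNTA
YSEGKPSAIASRGWIEIGQRDDLKGFDTVKLVVDSATGDAKNPQFGPESKMVGVRKTREF
WVRGNVIATDIRAVPRDVGKLYERNRADKSKGDAKIASIRGLNISTKIDSLGVEGGVVDG
FSMDPFVAANVVDMRMANLAKKEIPTAVLHQVYKEVQPFADSDSDNDQKTPAVFPKAFYA
PVVFWIAYLRELKISNEGTDREVADGESIAVKSRAQTAKVGFFLTTMVKPGDRTIFSINL
LAGQIHTNAQLNPPTKSLPIDWLQDLSLTA
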