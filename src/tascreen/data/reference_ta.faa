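>relB_ec|relB|antitoxin
MGSINLRIDDELKARSYAALEKMGVTPSEALRLMLEYIADNERLPFKQTLLSDEDAELVEIVKERLRNPKPVRVTLDEL
>relB_cb|relB|antitoxin
MGSVNLRIDDELKTRSYAALEKMGITPSEALRLMLDYIAENERLPFKQTLLSEEDAELVEIVKARLRNPKPVRVTLDEL
>relE_ec|relE|toxin
MAYFLDFDERALKEWRKLGSTVREQLKKKLVEVLESPRIEANKLRGMPDCYKIKLRSSGYRLVYQVIDEKVVVFVISVGKRERSEVYSEAVKRIL
>mazE_ec|mazE|antitoxin
MIHSSVKRWGNSPAVRIPATLMQALNLNIDDEVKLDLVDGKLIIEPVRKEPVFTLAELVNDITPENLHENIDWGEPKDKEVW
>mazF_ec|mazF|toxin
MVSRYVPDMGDLIWVDFDPTKGSEQAGHRPAVVLSPFMYNNKTGMCLCVPCTTQSKGYPFEVVLSGQERDGVALADQVKSIAWRARGATKKGTVAPEELQLIKAKINVLIG
>yefM_ec|yefM|antitoxin
MRTISYSEARQNLSATMMKAVEDHAPILITRQNGEACVLMSLEEYNSLEETAYLLRSPANARRLMDSIDSLKSGKGTEKDIIE
>yoeB_ec|yoeB|toxin
MKLIWSEESWDDYLYWQETDKRIVKKINELIKDTRRTPFEGKGKPEPLKHNLSGFWSRRITEEHRLVYAVTDDSLLIAACRYHY
>vapB_mt|vapB|antitoxin
MRTTVTLDDDVVRRAQALTGIREKSALVNEALRTLIERESARRLAELGGSEPELSTVPRRRGDVL
>vapC_mt|vapC|toxin
MIVLDTNVLSELMRPQPDPRVVAWLDSVDASELFVSAITVAELRFGVALLPEGRRRDDLQAAVDQMVADYADRILPFDTAAAEVYGTIAAAARAHGRPIAAADAQIAAIAHSRGATVATRNTRDFEGTGVDLVNPWQA
>phd_p1|phd|antitoxin
MQSINFRTARGNLSEVLNNVEAGEEVEITRRGREPAVIVSKATFEAYKKAALDAEFASLFDTLDSTNKELVNR
>doc_p1|doc|toxin
MRYITHQEVLDIHDELIATHGGLDGVRDLGLLESALARPQTTVFGQDAYPSLHEKAAALLHSIVRNHALVDGNKRLGWLATLVFLRLNGYDLEVPESEAYDLVIGVATGEMDVAEIASWLRSHTREV
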